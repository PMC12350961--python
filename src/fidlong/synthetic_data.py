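"""Synthetic BY x RM segregant panels with Orgel-coupled traits.

Generates every input the analysis pipeline consumes, with known ground
truth, so each stage can be tested end to end without external data:

* recombinant haploid genotypes (Markov chain along each chromosome:
  first marker Bernoulli(0.5), later markers switch parent with the
  per-interval recombination probability);
* per-strain baseline error rates E with planted additive QTL effects,
  an "other-cause" lifespan, and the realized lifespan
  min(other-cause, error-catastrophe cap) — exactly the trapezoid
  geometry of the error-catastrophe model;
* outgrowth OD600 plate curves whose threshold-crossing times encode a
  planted survival schedule (crossings are snapped to the 10-minute
  sampling grid so the grid-based first-crossing rule recovers the
  schedule exactly in the noise-free limit);
* dual-luciferase RLU tables whose activity ratios encode E and whose
  default scales sit inside the RLU gates.

One master seed fixes everything via spawned child seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cls_pipeline import BLANK_STRAIN, survival_integral
from .orgel_model import OrgelParams, max_lifespan
from .qtl_mapping import GenotypeMatrix

__all__ = [
    "PlantedQTL",
    "SynthConfig",
    "GroundTruth",
    "gen_genotypes",
    "gen_traits",
    "gen_growth_curves",
    "gen_rlu",
    "generate_all",
]


@dataclass(frozen=True)
class PlantedQTL:
    """An additive allelic effect planted at one marker.

    ``effect`` is added to the trait for strains carrying the RM allele
    (call = 1); trait is "error_rate" (units of E) or "lifespan" (model
    time units, applied to the other-cause lifespan).  ``marker="auto"``
    resolves to the middle marker of chromosome 10 (or of the last
    chromosome on smaller panels) at generation time.
    """

    marker: str
    trait: str
    effect: float


def _default_qtls() -> tuple[PlantedQTL, ...]:
    # one pleiotropic locus: the RM allele lowers the baseline error rate
    # by 0.3*(U-L) (lengthening lifespan through the error-catastrophe
    # cap) and directly extends the other-cause lifespan by 4 model time
    # units (~30% of lifespan variance) — a major-effect QTL, the regime
    # in which a locus stays detectable on the long-lived half of a
    # 120-strain panel; the cap coupling alone is far too weak a signal
    # for a linkage scan of that size
    p = OrgelParams()
    return (
        PlantedQTL("auto", "error_rate", -0.3 * (p.U - p.L)),
        PlantedQTL("auto", "lifespan", 4.0),
    )


def resolve_marker(geno: GenotypeMatrix, config: "SynthConfig", marker: str) -> str:
    """Resolve a planted-QTL marker name, expanding the "auto" sentinel."""
    if marker != "auto":
        return marker
    chrom = f"chr{min(10, config.n_chromosomes)}"
    on_chrom = geno.markers.index[geno.markers["chrom"] == chrom]
    return on_chrom[len(on_chrom) // 2]


@dataclass(frozen=True)
class SynthConfig:
    """Panel layout, model constants and noise levels for generation."""

    n_strains: int = 120
    n_chromosomes: int = 16
    markers_per_chromosome: int = 30
    marker_spacing: int = 25_000
    recomb_prob: float = 0.1
    orgel: OrgelParams = field(default_factory=OrgelParams)
    planted_qtls: tuple[PlantedQTL, ...] = field(default_factory=_default_qtls)
    mean_error_rate: float | None = None  # default (L+U)/2
    error_rate_sd: float | None = None  # strain-level noise; default 0.15*(U-L)
    trait_cv: float = 0.05  # replicate-level multiplicative noise
    od_noise_sd: float = 0.002  # additive OD600 noise per reading
    n_bio: int = 3
    n_tech: int = 3
    days: tuple[int, ...] = (2, 4, 6, 9, 12, 15)
    # outgrowth geometry (minutes)
    t2_target: float = 450.0
    doubling_time: float = 90.0
    t_step: float = 10.0
    t_ref: float = 50.0
    horizon: float = 720.0
    threshold: float = 0.3
    background: float = 0.08
    capacity: float = 1.3
    # luciferase scales
    renilla_scale: float = 2e7
    wt_firefly_ratio: float = 0.15
    # lifespan (model units) -> survival half-life (days) mapping
    half_life_offset: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_strains, self.n_chromosomes, self.markers_per_chromosome) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.recomb_prob <= 1):
            raise ValueError("recombination probability must be in [0, 1]")

    @property
    def mu_e(self) -> float:
        if self.mean_error_rate is not None:
            return self.mean_error_rate
        return 0.5 * (self.orgel.L + self.orgel.U)

    @property
    def sigma_e(self) -> float:
        if self.error_rate_sd is not None:
            return self.error_rate_sd
        return 0.15 * (self.orgel.U - self.orgel.L)


@dataclass(frozen=True)
class GroundTruth:
    """Per-strain truth table underlying all generated observations.

    Columns: E (baseline error rate), max_lifespan, other_lifespan,
    lifespan (= min of the two), half_life (survival half-life in days),
    cls_true (survival integral of the ideal schedule), S_<day> columns,
    clipped (E hit the [L, U] bounds).
    """

    table: pd.DataFrame
    days: tuple[int, ...]
    config: SynthConfig


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def gen_genotypes(config: SynthConfig, seed: int | None = None) -> GenotypeMatrix:
    """Recombinant haploid genotypes for the panel (0 = BY, 1 = RM)."""
    rng = np.random.default_rng(seed)
    n, m = config.n_strains, config.markers_per_chromosome
    blocks = []
    names = []
    for c in range(1, config.n_chromosomes + 1):
        calls = np.empty((n, m))
        calls[:, 0] = rng.integers(0, 2, size=n)
        flips = rng.random(size=(n, m - 1)) < config.recomb_prob if m > 1 else None
        for j in range(1, m):
            calls[:, j] = np.where(flips[:, j - 1], 1 - calls[:, j - 1], calls[:, j - 1])
        blocks.append(calls)
        names.extend(f"chr{c}:{config.marker_spacing * (j + 1)}" for j in range(m))
    calls = pd.DataFrame(
        np.hstack(blocks),
        index=pd.Index([f"seg{i:04d}" for i in range(n)], name="strain"),
        columns=names,
    )
    return GenotypeMatrix.from_frame(calls)


def gen_traits(
    geno: GenotypeMatrix, config: SynthConfig, seed: int | None = None
) -> tuple[GroundTruth, pd.DataFrame]:
    """Ground-truth traits plus a replicate-level trait table.

    E = clip(mu_E + planted effects + strain noise, L, U); the
    other-cause lifespan is uniform on [0, max_lifespan(L)] plus any
    planted lifespan effects (clipped at 0); the realized lifespan is
    min(other-cause, max_lifespan(E)).  Replicate observations carry
    multiplicative lognormal noise at the configured CV.
    """
    rng = np.random.default_rng(seed)
    p = config.orgel
    n = len(geno.calls)
    E = config.mu_e + rng.normal(0.0, config.sigma_e, size=n)
    other = rng.uniform(0.0, max_lifespan(p, p.L), size=n)
    for q in config.planted_qtls:
        g = geno.calls[resolve_marker(geno, config, q.marker)].to_numpy(dtype=float)
        g = np.where(np.isnan(g), 0.5, g)
        if q.trait == "error_rate":
            E = E + q.effect * g
        elif q.trait == "lifespan":
            other = other + q.effect * g
        else:
            raise ValueError(f"unknown planted trait {q.trait!r}")
    clipped = (E < p.L) | (E > p.U)
    E = np.clip(E, p.L, p.U)
    other = np.clip(other, 0.0, None)
    cap = max_lifespan(p, E)
    lifespan = np.minimum(other, cap)
    half_life = config.half_life_offset + lifespan

    days = np.asarray(config.days, dtype=float)
    sched = 2.0 ** (-(days[None, :] - days[0]) / half_life[:, None])
    cls_true = np.trapezoid(sched, days, axis=1)

    table = pd.DataFrame(
        {
            "E": E,
            "max_lifespan": cap,
            "other_lifespan": other,
            "lifespan": lifespan,
            "half_life": half_life,
            "cls_true": cls_true,
            "clipped": clipped,
        },
        index=geno.calls.index,
    )
    for j, d in enumerate(config.days):
        table[f"S_{d}"] = sched[:, j]

    reps = []
    for b in range(1, config.n_bio + 1):
        reps.append(
            pd.DataFrame(
                {
                    "strain": table.index,
                    "replicate": b,
                    "cls": cls_true * _lognormal_factor(rng, config.trait_cv, n),
                    "error_rate": E * _lognormal_factor(rng, config.trait_cv, n),
                }
            )
        )
    rep_df = pd.concat(reps, ignore_index=True)
    return GroundTruth(table=table, days=config.days, config=config), rep_df


def _crossing_times(
    half_life: float, config: SynthConfig
) -> dict[int, float]:
    """Planted threshold-crossing time per aging day, snapped to the
    sampling grid when it falls within the horizon."""
    out = {}
    d0 = config.days[0]
    for d in config.days:
        t_n = config.t2_target + config.doubling_time * (d - d0) / half_life
        if t_n <= config.horizon:
            t_n = round(t_n / config.t_step) * config.t_step
            t_n = min(max(t_n, config.t_ref + config.t_step), config.horizon)
        out[d] = t_n
    return out


def gen_growth_curves(
    truth: GroundTruth, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format outgrowth plate records plus the planted CLS table.

    Each well's background-corrected OD is a pure exponential with the
    strain's doubling time, scaled so the t50-normalized curve crosses
    the threshold exactly at the planted (grid-snapped) time; wells whose
    crossing exceeds the 12-h horizon exercise the extrapolation path.
    Returns (plate_df, planted_df) where planted_df holds, per strain and
    biological replicate, the survival schedule and CLS implied by the
    generated curves (the round-trip oracle).
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, config.horizon + config.t_step / 2, config.t_step)
    pow_t = 2.0 ** (times / config.doubling_time)
    pow_ref = 2.0 ** (config.t_ref / config.doubling_time)
    d0 = config.days[0]

    records = []
    planted = []
    for strain, row in truth.table.iterrows():
        for b in range(1, config.n_bio + 1):
            h_b = row["half_life"] * float(
                _lognormal_factor(rng, config.trait_cv, None)
            )
            t_cross = _crossing_times(h_b, config)
            surv = {
                d: 2.0 ** (-(t_cross[d] - t_cross[d0]) / config.doubling_time)
                for d in config.days
            }
            cls_planted = survival_integral(
                list(config.days), [surv[d] for d in config.days]
            )
            planted.append(
                {
                    "strain": strain,
                    "bio_rep": b,
                    "cls_planted": cls_planted,
                    **{f"S_{d}": surv[d] for d in config.days},
                }
            )
            for d in config.days:
                amp = (
                    config.threshold
                    / (2.0 ** (t_cross[d] / config.doubling_time) - pow_ref)
                    * (1.0 + 1e-9)
                )
                od = config.background + np.minimum(config.capacity, amp * pow_t)
                for tech in range(1, config.n_tech + 1):
                    noisy = od + (
                        rng.normal(0.0, config.od_noise_sd, size=len(times))
                        if config.od_noise_sd > 0
                        else 0.0
                    )
                    records.append(
                        pd.DataFrame(
                            {
                                "plate": f"day{d}",
                                "well": f"{strain}_b{b}_t{tech}",
                                "strain": strain,
                                "bio_rep": b,
                                "tech_rep": tech,
                                "aging_day": d,
                                "time_min": times,
                                "od600": noisy,
                            }
                        )
                    )
    # three cell-free blank wells per plate (aging day)
    for d in config.days:
        for tech in range(1, 4):
            od = config.background + (
                rng.normal(0.0, config.od_noise_sd, size=len(times))
                if config.od_noise_sd > 0
                else 0.0
            )
            records.append(
                pd.DataFrame(
                    {
                        "plate": f"day{d}",
                        "well": f"blank_t{tech}",
                        "strain": BLANK_STRAIN,
                        "bio_rep": 0,
                        "tech_rep": tech,
                        "aging_day": d,
                        "time_min": times,
                        "od600": od,
                    }
                )
            )
    plate_df = pd.concat(records, ignore_index=True)
    planted_df = pd.DataFrame(planted)
    return plate_df, planted_df


def gen_rlu(
    truth: GroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """Dual-luciferase RLU table encoding each strain's error rate.

    Renilla ~ scale * lognormal; wildtype Firefly = ratio * Renilla *
    lognormal; mutant Firefly = E * ratio * Renilla * lognormal, so the
    mutant/wildtype activity ratio equals E exactly when noise is off.
    Default scales keep >= 99% of draws inside the RLU gates.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    rows = []
    for strain, row in truth.table.iterrows():
        E = row["E"]
        for reporter in ("mut", "wt"):
            for b in range(1, config.n_bio + 1):
                for tech in range(1, config.n_tech + 1):
                    renilla = config.renilla_scale * float(
                        _lognormal_factor(rng, config.trait_cv, None)
                    )
                    act = config.wt_firefly_ratio * (E if reporter == "mut" else 1.0)
                    firefly = act * renilla * float(
                        _lognormal_factor(rng, config.trait_cv, None)
                    )
                    rows.append(
                        {
                            "strain": strain,
                            "reporter": reporter,
                            "bio_rep": b,
                            "tech_rep": tech,
                            "firefly_rlu": firefly,
                            "renilla_rlu": renilla,
                        }
                    )
    return pd.DataFrame(rows)


def generate_all(config: SynthConfig, seed: int | None = None) -> dict:
    """Generate the full linked dataset from one master seed.

    Returns a dict with keys geno, truth, replicate_traits, plate,
    planted_cls, rlu; every stage's oracle is included.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_traits, s_curves, s_rlu = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    geno = gen_genotypes(config, seed=s_geno)
    truth, rep_df = gen_traits(geno, config, seed=s_traits)
    plate_df, planted_df = gen_growth_curves(truth, seed=s_curves)
    rlu_df = gen_rlu(truth, seed=s_rlu)
    return {
        "geno": geno,
        "truth": truth,
        "replicate_traits": rep_df,
        "plate": plate_df,
        "planted_cls": planted_df,
        "rlu": rlu_df,
    }
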