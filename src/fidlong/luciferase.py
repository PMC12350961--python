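"""Translation error rates from dual-luciferase reporter tables.

The reporter is a Renilla-Firefly fusion.  The wildtype Firefly carries
Lys (AAA) at position 529; the mutant carries Arg (AGG) and is only
luminescent when the codon is mistranslated back to Lys, so the
mutant-to-wildtype ratio of Renilla-normalized Firefly activities
measures the translation error rate.  Raw relative luminescence units
(RLU) are gated to the instrument's informative range, technical and
biological replicates are CV-filtered (CV <= 0.2), and strains whose
apparent error rate exceeds 1e-2 are discarded as assay failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cls_pipeline import cv_filter

__all__ = [
    "RLUGates",
    "rlu_gate",
    "normalized_activity",
    "aggregate_activity",
    "translation_error_rate",
    "error_rate_dispersion",
    "estimate_error_rates",
]

WILDTYPE = "wt"
MUTANT = "mut"


@dataclass(frozen=True)
class RLUGates:
    """Inclusive RLU bounds defining informative measurements."""

    mut_firefly: tuple[float, float] = (5e2, 1e4)
    wt_firefly_min: float = 1e6
    renilla: tuple[float, float] = (5e6, 1e8)


DEFAULT_GATES = RLUGates()


def rlu_gate(
    reporter: str, firefly: float, renilla: float, gates: RLUGates = DEFAULT_GATES
) -> tuple[bool, str]:
    """Check one measurement against the RLU gates.

    Returns (passed, reason); the reason names the first violated bound.
    Bounds are closed intervals ("between" read as inclusive).
    """
    if not (np.isfinite(firefly) and np.isfinite(renilla)) or firefly < 0 or renilla < 0:
        return False, "non-finite-or-negative-rlu"
    if renilla < gates.renilla[0]:
        return False, "renilla-below-lower-bound"
    if renilla > gates.renilla[1]:
        return False, "renilla-above-upper-bound"
    if reporter == MUTANT:
        if firefly < gates.mut_firefly[0]:
            return False, "mutant-firefly-below-lower-bound"
        if firefly > gates.mut_firefly[1]:
            return False, "mutant-firefly-above-upper-bound"
    elif reporter == WILDTYPE:
        if firefly < gates.wt_firefly_min:
            return False, "wildtype-firefly-below-lower-bound"
    else:
        raise ValueError(f"reporter must be {WILDTYPE!r} or {MUTANT!r}, got {reporter!r}")
    return True, "pass"


def normalized_activity(firefly: float, renilla: float) -> float:
    """Protein-abundance-normalized Firefly activity, firefly/renilla."""
    if renilla <= 0:
        raise ValueError(f"renilla RLU must be positive, got {renilla}")
    return firefly / renilla


def aggregate_activity(
    df: pd.DataFrame,
    cv_max: float = 0.2,
    gates: RLUGates = DEFAULT_GATES,
) -> tuple[pd.Series, float, list[str]]:
    """Per-biological-replicate activities and their mean for one
    strain x reporter block.

    Gates are applied first; no gated-out value influences any mean.
    Technical replicates within a biological replicate, and then the
    biological replicate values, are CV-filtered at ``cv_max``.  Returns
    (kept per-bio-rep activities, strain mean, flags); the mean is NaN
    and the flags say why when everything is discarded.
    """
    flags: list[str] = []
    reporter = df["reporter"].iloc[0]
    bio_values: dict = {}
    for bio, bgrp in df.groupby("bio_rep", sort=True):
        passed = []
        for _, row in bgrp.iterrows():
            ok, reason = rlu_gate(reporter, row["firefly_rlu"], row["renilla_rlu"], gates)
            if ok:
                passed.append(normalized_activity(row["firefly_rlu"], row["renilla_rlu"]))
            else:
                flags.append(f"bio{bio}:{reason}")
        if len(passed) < 2:
            flags.append(f"bio{bio}:fewer-than-2-gated-tech-reps")
            continue
        res = cv_filter(np.array(passed), cv_max)
        if res.reason == "all-discarded":
            flags.append(f"bio{bio}:tech-all-discarded")
            continue
        if res.reason == "dropped-outlier":
            flags.append(f"bio{bio}:tech-rep-dropped")
        bio_values[bio] = float(np.mean(res.kept))

    series = pd.Series(bio_values, dtype=float)
    if series.empty:
        flags.append("all-bio-reps-discarded")
        return series, math.nan, flags
    if len(series) >= 2:
        res = cv_filter(series.to_numpy(), cv_max)
        if res.reason == "all-discarded":
            flags.append("bio-all-discarded")
            return series.iloc[0:0], math.nan, flags
        if res.reason == "dropped-outlier":
            flags.append("bio-rep-dropped")
        series = series.iloc[res.kept_idx]
    else:
        flags.append("single-bio-rep")
    return series, float(series.mean()), flags


def translation_error_rate(
    mut_activity: float, wt_activity: float, max_rate: float = 1e-2
) -> tuple[float, str]:
    """Ratio of mutant to wildtype Firefly activity.

    Rates above ``max_rate`` are flagged "exceeds-max-rate" (the strain
    is treated as an assay failure downstream); a zero mutant activity is
    retained but flagged.
    """
    if wt_activity <= 0:
        raise ValueError(f"wildtype activity must be positive, got {wt_activity}")
    rate = mut_activity / wt_activity
    if rate > max_rate:
        return rate, "exceeds-max-rate"
    if rate == 0:
        return rate, "zero-mutant-activity"
    return rate, "ok"


def error_rate_dispersion(
    mut_activities, wt_activities
) -> tuple[np.ndarray, float, list[str]]:
    """Per-pair error rates and their sample SD.

    Biological replicate i of the mutant reporter is paired with
    replicate i of the wildtype reporter in index order (the pairing is
    a convention, not part of the assay).  Mismatched counts pair up to
    the shorter list; a single pair yields an undefined SD.
    """
    mut = np.asarray(mut_activities, dtype=float)
    wt = np.asarray(wt_activities, dtype=float)
    flags: list[str] = []
    k = min(len(mut), len(wt))
    if len(mut) != len(wt):
        flags.append("replicate-count-mismatch")
    if k == 0:
        flags.append("no-replicate-pairs")
        return np.array([]), math.nan, flags
    rates = mut[:k] / wt[:k]
    if k < 2:
        flags.append("sd-undefined-single-pair")
        return rates, math.nan, flags
    return rates, float(np.std(rates, ddof=1)), flags


def estimate_error_rates(
    rlu_df: pd.DataFrame,
    cv_max: float = 0.2,
    max_rate: float = 1e-2,
    gates: RLUGates = DEFAULT_GATES,
) -> pd.DataFrame:
    """Per-strain translation error rates from a long RLU table.

    Expects columns strain, reporter ("wt"|"mut"), bio_rep, tech_rep,
    firefly_rlu, renilla_rlu.  The strain error rate is the ratio of the
    strain-averaged mutant and wildtype activities; the per-pair rates
    from index-matched biological replicates provide the SD.  Strains
    lacking a retained estimate for either reporter, or exceeding
    ``max_rate``, get error_rate = NaN with an explanatory flag.
    """
    rows = []
    for strain, sgrp in rlu_df.groupby("strain", sort=True):
        flags: list[str] = []
        per_rep: dict[str, pd.Series] = {}
        means: dict[str, float] = {}
        for reporter in (MUTANT, WILDTYPE):
            block = sgrp[sgrp["reporter"] == reporter]
            if block.empty:
                flags.append(f"{reporter}:no-measurements")
                continue
            series, mean, agg_flags = aggregate_activity(block, cv_max, gates)
            per_rep[reporter] = series
            means[reporter] = mean
            flags.extend(f"{reporter}:{f}" for f in agg_flags)
        rate = math.nan
        sd = math.nan
        n_pairs = 0
        if (
            MUTANT in means
            and WILDTYPE in means
            and not math.isnan(means[MUTANT])
            and not math.isnan(means[WILDTYPE])
        ):
            rate, reason = translation_error_rate(means[MUTANT], means[WILDTYPE], max_rate)
            if reason == "exceeds-max-rate":
                flags.append(reason)
                rate = math.nan
            elif reason != "ok":
                flags.append(reason)
            if not math.isnan(rate):
                pair_rates, sd, disp_flags = error_rate_dispersion(
                    per_rep[MUTANT].to_numpy(), per_rep[WILDTYPE].to_numpy()
                )
                n_pairs = len(pair_rates)
                flags.extend(disp_flags)
        else:
            flags.append("no-estimate")
        rows.append(
            {
                "strain": strain,
                "error_rate": rate,
                "sd": sd,
                "n_pairs": n_pairs,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
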