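"""Relative qPCR quantification: amplification efficiency from standard-curve
slope, 2^(-dCt) relative levels against the mean of reference genes, and the
replicate structure used for developmental expression profiles (technical
replicates averaged within each biological replicate, stage value = median
across biological replicates).
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Sequence

import numpy as np
import pandas as pd


class QpcrError(ValueError):
    pass


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) in fold per cycle.

    A valid standard curve has a negative slope (about -3.32 for a perfectly
    doubling reaction); a positive slope is accepted with a warning since it
    cannot come from a real dilution series.
    """
    if slope == 0:
        raise QpcrError("standard-curve slope must be non-zero")
    if slope > 0:
        warnings.warn("positive standard-curve slope: invalid curve", stacklevel=2)
    return 10.0 ** (-1.0 / slope)


def standard_curve_slope(log10_dilutions: Sequence[float], cts: Sequence[float]) -> float:
    """Least-squares slope of Ct against log10 dilution."""
    x = np.asarray(log10_dilutions, dtype=float)
    y = np.asarray(cts, dtype=float)
    if x.size < 2:
        raise QpcrError("need at least two dilution points")
    return float(np.polyfit(x, y, 1)[0])


def relative_expression(ct_target: float, ct_refs: Sequence[float]) -> float:
    """2^(-dCt) with dCt = Ct_target - mean(Ct_references)."""
    refs = [float(c) for c in ct_refs]
    if not refs:
        raise QpcrError("at least one reference Ct is required")
    if ct_target <= 0 or any(c <= 0 for c in refs):
        raise QpcrError("Ct values must be positive")
    dct = float(ct_target) - float(np.mean(refs))
    return 2.0 ** (-dct)


def summarize_stage(
    measurements: pd.DataFrame,
    reference_genes: Sequence[str] = ("rps9", "sams"),
) -> pd.DataFrame:
    """Per-stage, per-gene relative levels from a long-format Ct table.

    Input columns: stage, gene, bio_rep, tech_rep, Ct.  Technical replicates
    are averaged (mean Ct) within each biological replicate *before* the
    dCt step; the stage value is the median across biological replicates of
    the per-replicate relative level.  Replicate spread (min/max level) is
    reported alongside.  Genes or stages without any reference measurement
    are dropped with a warning.
    """
    required = {"stage", "gene", "bio_rep", "tech_rep", "Ct"}
    missing = required - set(measurements.columns)
    if missing:
        raise QpcrError(f"Ct table lacks columns: {sorted(missing)}")
    refs = set(reference_genes)
    mean_ct = (
        measurements.groupby(["stage", "gene", "bio_rep"], sort=False)["Ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for stage, stage_df in mean_ct.groupby("stage", sort=False):
        ref_by_rep: Dict[object, float] = {}
        for rep, rep_df in stage_df.groupby("bio_rep"):
            ref_cts = rep_df[rep_df["gene"].isin(refs)]["Ct"]
            if len(ref_cts) == 0:
                continue
            ref_by_rep[rep] = float(ref_cts.mean())
        for gene, gene_df in stage_df.groupby("gene"):
            if gene in refs:
                continue
            levels = []
            for _, row in gene_df.iterrows():
                rep = row["bio_rep"]
                if rep not in ref_by_rep:
                    continue
                levels.append(relative_expression(row["Ct"], [ref_by_rep[rep]]))
            if not levels:
                warnings.warn(
                    f"no usable replicates for {gene!r} at stage {stage!r}; omitted",
                    stacklevel=2,
                )
                continue
            rows.append(
                (
                    stage,
                    gene,
                    float(np.median(levels)),
                    len(levels),
                    float(min(levels)),
                    float(max(levels)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["stage", "gene", "median_level", "n_bio_reps", "min_level", "max_level"],
    )
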