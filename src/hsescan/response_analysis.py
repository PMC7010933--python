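"""Heat-responsive gene calling and response-magnitude (MFH) statistic.

A gene is heat-responsive in an organ when it is differentially
expressed at any of the five stress time points (5, 10, 30 min, 1 h,
4 h): fold change >= 2.0 and FDR-adjusted p < 0.05.  By default fold
change enters as the directional magnitude max(FC, 1/FC), so two-fold
down-regulation also qualifies; ``direction="up"`` restricts to
induction only.

The response magnitude MFH of a responsive gene is its maximal fold
change over the five time points, z-standardized within the organ's
responsive-gene set (mean 0, sd 1).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

TIMEPOINTS = ("5m", "10m", "30m", "1h", "4h")

DE_COLUMNS = ("gene_id", "organ", "timepoint", "fold_change", "adj_p")


def _validate_de(de: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if (de["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive")
    if ((de["adj_p"] < 0) | (de["adj_p"] > 1)).any():
        raise ValueError("adj_p must lie in [0, 1]")
    dup = de.duplicated(subset=["gene_id", "organ", "timepoint"])
    if dup.any():
        first = de.loc[dup, ["gene_id", "organ", "timepoint"]].iloc[0]
        raise ValueError(
            f"duplicate DE row for {tuple(first)}; one row per "
            "(gene, organ, timepoint) expected"
        )
    return de


def directional_magnitude(fc: pd.Series | np.ndarray) -> np.ndarray:
    """max(FC, 1/FC): two-fold up and two-fold down both map to 2."""
    fc = np.asarray(fc, dtype=float)
    return np.maximum(fc, 1.0 / fc)


def call_responsive(
    de: pd.DataFrame,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    direction: str = "both",
) -> set[tuple[str, str]]:
    """Set of (gene_id, organ) responsive at >= 1 time point."""
    de = _validate_de(de)
    if direction == "both":
        mag = directional_magnitude(de["fold_change"])
    elif direction == "up":
        mag = de["fold_change"].to_numpy(dtype=float)
    else:
        raise ValueError(f"direction must be 'both' or 'up', got {direction!r}")
    hit = (mag >= fc_min) & (de["adj_p"].to_numpy() < alpha)
    pairs = de.loc[hit, ["gene_id", "organ"]].drop_duplicates()
    return set(map(tuple, pairs.itertuples(index=False)))


def compute_mfh(
    de: pd.DataFrame,
    responsive: set[tuple[str, str]],
    direction: str = "both",
) -> pd.DataFrame:
    """Max fold change and its within-organ z-score for responsive genes.

    Requires at least two responsive genes per organ and nonzero spread
    of their maxima (the z-score is undefined otherwise).
    """
    de = _validate_de(de)
    if not responsive:
        raise ValueError("empty responsive set")
    key = list(zip(de["gene_id"], de["organ"]))
    sub = de.loc[[k in responsive for k in key]].copy()
    if direction == "both":
        sub["mag"] = directional_magnitude(sub["fold_change"])
    else:
        sub["mag"] = sub["fold_change"].astype(float)
    out = (
        sub.groupby(["organ", "gene_id"], as_index=False)["mag"]
        .max()
        .rename(columns={"mag": "max_fc"})
    )
    frames = []
    for organ, grp in out.groupby("organ"):
        if len(grp) < 2:
            raise ValueError(
                f"organ {organ!r} has a single responsive gene; "
                "standardization undefined"
            )
        sd = grp["max_fc"].std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"organ {organ!r}: all maximal fold changes identical; "
                "standardization undefined"
            )
        grp = grp.copy()
        grp["mfh"] = (grp["max_fc"] - grp["max_fc"].mean()) / sd
        frames.append(grp)
    return (
        pd.concat(frames, ignore_index=True)
        .loc[:, ["gene_id", "organ", "max_fc", "mfh"]]
        .sort_values(["organ", "gene_id"], ignore_index=True)
    )


def adjust_bh(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_response_rates(
    counts: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Per-class response rates from {class: (responsive, total)}."""
    rows = []
    for cls, (resp, total) in counts.items():
        if total <= 0 or resp > total:
            raise ValueError(f"bad counts for class {cls!r}: {resp}/{total}")
        rows.append(
            {
                "gene_class": cls,
                "responsive": resp,
                "total": total,
                "percent": 100.0 * resp / total,
            }
        )
    return pd.DataFrame(rows).set_index("gene_class")
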