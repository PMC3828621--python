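"""Joining site statistics with solvent accessibility.

The central object is a per-site table (one row per structure position present
in both the alignment's site map and the RSA profile) holding RSA, exposure
class, per-condition site entropies and divergences. From it we compute the
entropy-RSA correlation per protein and condition, exposure-class entropy
summaries, and exposure-stratified amino-acid frequencies pooled over
proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .msa_io import Alignment, CountMatrix, SiteMap, column_counts, DEFAULT_ALPHABET
from .site_statistics import EntropyVector, site_entropy, site_frequencies
from .solvent_accessibility import (
    ExposureScheme,
    RSAProfile,
    THREE_CLASS,
    TWO_CLASS,
    classify_exposure,
)

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Entropy-RSA correlation for one protein and condition."""

    protein_id: str
    condition: str
    coefficient: float
    n_sites: int
    method: str  # "pearson" | "spearman"

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError("|coefficient| must be <= 1")
        if self.n_sites < 3:
            raise ValueError("correlation needs at least 3 sites")


def join_site_table(
    entropies: dict[str, EntropyVector],
    positions: np.ndarray,
    rsa: RSAProfile,
    scheme: ExposureScheme = THREE_CLASS,
    divergences: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Build the per-site table joining entropies (keyed by condition) with RSA.

    Positions present on only one side are logged and excluded; the returned
    frame has one row per shared structure position, columns ``position``,
    ``rsa``, ``exposure_class``, ``entropy_<condition>`` and optionally
    ``kl_<condition>`` / ``rank_kl_<condition>``.
    """
    rsa_map = rsa.rsa_by_position()
    positions = np.asarray(positions)
    shared = [i for i, p in enumerate(positions) if int(p) in rsa_map]
    n_dropped = len(positions) - len(shared) + len(set(rsa_map) - set(positions.tolist()))
    if n_dropped:
        logger.info("%d positions excluded from the site table (present on one side only)", n_dropped)
    rows = {
        "position": positions[shared],
        "rsa": [rsa_map[int(positions[i])] for i in shared],
    }
    df = pd.DataFrame(rows)
    df["exposure_class"] = [classify_exposure(r, scheme) for r in df["rsa"]]
    for cond, ev in entropies.items():
        if len(ev.values) != len(positions):
            raise ValueError(f"entropy vector for {cond!r} does not match positions")
        df[f"entropy_{cond}"] = ev.values[shared]
    if divergences:
        for name, vals in divergences.items():
            vals = np.asarray(vals)
            if len(vals) != len(positions):
                raise ValueError(f"divergence vector {name!r} does not match positions")
            df[name] = vals[shared]
    return df


def entropy_rsa_correlation(
    table: pd.DataFrame,
    condition: str,
    method: str = "pearson",
    protein_id: str = "",
) -> CorrelationResult:
    """Correlation between per-site RSA and site entropy of one condition.

    Raises on constant input on either axis (the correlation is undefined and
    must be reported as missing, never coerced to 0).
    """
    col = f"entropy_{condition}"
    if col not in table.columns:
        raise KeyError(f"no entropy column for condition {condition!r}")
    sub = table[["rsa", col]].dropna()
    x = sub["rsa"].to_numpy(float)
    y = sub[col].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 sites with finite entropy and RSA")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: constant RSA or entropy")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(protein_id, condition, float(r), len(x), method)


def class_entropy_by_protein(
    table: pd.DataFrame, conditions: list[str], scheme: ExposureScheme = THREE_CLASS
) -> pd.DataFrame:
    """Mean site entropy within each exposure class, per condition, for one protein."""
    records = []
    for cls in scheme.classes:
        mask = table["exposure_class"] == cls
        for cond in conditions:
            col = f"entropy_{cond}"
            vals = table.loc[mask, col]
            records.append(
                {
                    "exposure_class": cls,
                    "condition": cond,
                    "mean_entropy": float(vals.mean()) if len(vals) else np.nan,
                    "n_sites": int(mask.sum()),
                }
            )
    return pd.DataFrame(records)


def class_entropy_summary(per_protein: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-protein medians and means of class-wise mean entropies.

    ``per_protein`` holds one frame per protein from
    :func:`class_entropy_by_protein`; classes empty in a protein contribute
    NaN and are ignored in the median. Classes empty everywhere are reported
    with NaN medians (missing, not zero).
    """
    if not per_protein:
        raise ValueError("no proteins supplied")
    allp = pd.concat(per_protein, ignore_index=True)
    out = (
        allp.groupby(["exposure_class", "condition"], sort=False)["mean_entropy"]
        .agg(median="median", mean="mean", n_proteins="count")
        .reset_index()
    )
    return out


def class_aa_frequencies(
    alignments: list[Alignment],
    maps: list[SiteMap],
    rsa_profiles: list[RSAProfile],
    scheme: ExposureScheme = TWO_CLASS,
) -> pd.DataFrame:
    """Amino-acid frequencies pooled over all sites of all proteins, per class.

    Counts are raw (no pseudocount — these are descriptive frequencies);
    classes with no sites anywhere get NaN frequencies. Returns a frame with
    one row per (class, residue).
    """
    if not (len(alignments) == len(maps) == len(rsa_profiles)):
        raise ValueError("alignments, maps and rsa_profiles must be parallel lists")
    letters = DEFAULT_ALPHABET.letters
    pooled = {cls: np.zeros(20, dtype=np.int64) for cls in scheme.classes}
    for aln, smap, rsa in zip(alignments, maps, rsa_profiles):
        counts = column_counts(aln, smap)
        rsa_map = rsa.rsa_by_position()
        for i, pos in enumerate(counts.positions):
            r = rsa_map.get(int(pos))
            if r is None:
                continue
            pooled[classify_exposure(r, scheme)] += counts.counts[i]
    records = []
    for cls, vec in pooled.items():
        total = vec.sum()
        freqs = vec / total if total > 0 else np.full(20, np.nan)
        for j, aa in enumerate(letters):
            records.append({"exposure_class": cls, "aa": aa, "frequency": freqs[j]})
    return pd.DataFrame(records)


def summarize_conditions(per_protein: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Distribution summaries (min, quartiles, median, mean, max) per condition.

    ``per_protein`` has one row per (protein, condition) with numeric metric
    columns (mean entropy, mean KL, ...). Quartiles use linear interpolation.
    """
    if per_protein.empty:
        raise ValueError("no per-protein results to summarize")
    if value_cols is None:
        value_cols = [
            c
            for c in per_protein.columns
            if c not in ("protein_id", "condition")
            and pd.api.types.is_numeric_dtype(per_protein[c])
        ]
    records = []
    for cond, grp in per_protein.groupby("condition", sort=False):
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            records.append(
                {
                    "condition": cond,
                    "metric": col,
                    "n": int(vals.size),
                    "min": float(vals.min()),
                    "q1": float(np.percentile(vals, 25)),
                    "median": float(np.median(vals)),
                    "q3": float(np.percentile(vals, 75)),
                    "max": float(vals.max()),
                    "mean": float(vals.mean()),
                }
            )
    return pd.DataFrame(records)


def paired_comparison(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Generic paired comparison of two per-protein metric vectors (plumbing).

    Returns the mean difference and a paired t-test p-value. Provided as a
    convenience hook; no particular significance result is asserted anywhere
    in the package.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    t = stats.ttest_rel(x, y)
    return {"mean_diff": float(np.mean(x - y)), "t": float(t.statistic), "p": float(t.pvalue)}
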