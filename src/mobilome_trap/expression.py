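"""RPKM quantification, relative expression across timepoints, the
expressed-transposon filter, and ChIP enrichment versus a control.

RPKM = count / (feature length in kb x mapped library reads in millions).
Relative expression divides each library's RPKM by the baseline library's
(day 0); group-level ChIP enrichment pools length-corrected counts over the
members before forming the log2 ratio, which is robust to zero-count
members.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def rpkm_table(counts: pd.DataFrame, feature_lengths: Mapping[str, int],
               library_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Tidy expression records from a features x libraries count matrix.

    Returns columns feature_id, library_id, count, rpkm.
    """
    missing = [f for f in counts.index if f not in feature_lengths]
    if missing:
        raise ValueError(f"missing feature length for {missing[:3]}...")
    rows = []
    for lib in counts.columns:
        size_m = library_sizes[lib] / 1e6
        if size_m <= 0:
            raise ValueError(f"library size for {lib!r} must be > 0")
        for fid in counts.index:
            kb = feature_lengths[fid] / 1000
            if kb <= 0:
                raise ValueError(f"feature length for {fid!r} must be > 0")
            c = float(counts.at[fid, lib])
            rows.append((fid, lib, c, c / (kb * size_m)))
    return pd.DataFrame(rows, columns=["feature_id", "library_id", "count",
                                       "rpkm"])


def merge_split_features(counts: pd.DataFrame,
                         feature_lengths: Mapping[str, int],
                         merge_table: Mapping[str, Sequence[str]]):
    """Combine split gene models before RPKM: summed counts, summed lengths.

    ``merge_table`` maps a merged feature id to its parts; untouched features
    pass through.  Returns (counts, feature_lengths) with parts replaced.
    """
    merged_parts = {p for parts in merge_table.values() for p in parts}
    new_counts = counts.drop(index=[f for f in counts.index
                                    if f in merged_parts])
    lengths = {f: l for f, l in feature_lengths.items()
               if f not in merged_parts}
    for mid, parts in merge_table.items():
        new_counts.loc[mid] = counts.loc[list(parts)].sum(axis=0)
        lengths[mid] = sum(feature_lengths[p] for p in parts)
    return new_counts, lengths


def relative_expression(records: pd.DataFrame,
                        baseline_library: str) -> pd.DataFrame:
    """Add a ``relative`` column: rpkm / baseline-library rpkm per feature.

    A zero baseline leaves ``relative`` as NaN with ``baseline_zero`` True
    (flagged, not infinite).
    """
    if baseline_library not in set(records["library_id"]):
        raise ValueError(f"unknown baseline library {baseline_library!r}")
    base = (records[records["library_id"] == baseline_library]
            .set_index("feature_id")["rpkm"])
    out = records.copy()
    out["baseline_rpkm"] = out["feature_id"].map(base)
    if out["baseline_rpkm"].isna().any():
        raise ValueError("baseline library does not cover every feature")
    out["baseline_zero"] = out["baseline_rpkm"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = out["rpkm"] / out["baseline_rpkm"]
    out["relative"] = rel.where(~out["baseline_zero"], np.nan)
    return out


def expressed_transposon_filter(records: pd.DataFrame,
                                libraries: Sequence[str],
                                threshold_rpkm: float = 10.0) -> list[str]:
    """Features with rpkm strictly greater than the threshold in at least
    one of the named libraries."""
    present = set(records["library_id"])
    unknown = [l for l in libraries if l not in present]
    if unknown:
        raise ValueError(f"records do not cover libraries {unknown}")
    sel = records[records["library_id"].isin(libraries)]
    kept = sel[sel["rpkm"] > threshold_rpkm]["feature_id"].unique()
    return sorted(kept)


def chip_enrichment(chip_counts: Mapping[str, float],
                    control_counts: Mapping[str, float],
                    feature_lengths: Mapping[str, int],
                    chip_library_size: int,
                    control_library_size: int) -> pd.DataFrame:
    """Per-feature log2(chip RPKM / control RPKM) versus the control.

    Zero control RPKM leaves the enrichment NaN with ``control_zero`` True.
    """
    rows = []
    for fid in chip_counts:
        if fid not in control_counts:
            raise ValueError(f"feature {fid!r} missing from control")
        kb = feature_lengths[fid] / 1000
        chip_rpkm = chip_counts[fid] / (kb * chip_library_size / 1e6)
        ctrl_rpkm = control_counts[fid] / (kb * control_library_size / 1e6)
        if ctrl_rpkm == 0:
            rows.append((fid, chip_rpkm, ctrl_rpkm, np.nan, True))
        else:
            rows.append((fid, chip_rpkm, ctrl_rpkm,
                         np.log2(chip_rpkm / ctrl_rpkm) if chip_rpkm > 0
                         else -np.inf, False))
    return pd.DataFrame(rows, columns=["feature_id", "chip_rpkm",
                                       "control_rpkm", "log2_enrichment",
                                       "control_zero"])


def group_chip_enrichment(chip_counts: Mapping[str, float],
                          control_counts: Mapping[str, float],
                          feature_lengths: Mapping[str, int],
                          chip_library_size: int,
                          control_library_size: int,
                          groups: Mapping[str, Iterable[str]],
                          pooled: bool = True) -> pd.DataFrame:
    """Group-level enrichment.

    ``pooled`` (default) forms the ratio of summed length-corrected counts
    over the members; the alternative averages per-member log2 ratios
    (members with zero control are dropped from the mean).
    """
    per_feature = chip_enrichment(chip_counts, control_counts,
                                  feature_lengths, chip_library_size,
                                  control_library_size)
    per_feature = per_feature.set_index("feature_id")
    rows = []
    for gid, members in groups.items():
        members = list(members)
        if pooled:
            chip_rate = sum(chip_counts[m] / (feature_lengths[m] / 1000)
                            for m in members) / (chip_library_size / 1e6)
            ctrl_rate = sum(control_counts[m] / (feature_lengths[m] / 1000)
                            for m in members) / (control_library_size / 1e6)
            if ctrl_rate == 0:
                rows.append((gid, np.nan, True))
            else:
                rows.append((gid, float(np.log2(chip_rate / ctrl_rate))
                             if chip_rate > 0 else -np.inf, False))
        else:
            vals = per_feature.loc[[m for m in members], "log2_enrichment"]
            vals = vals[np.isfinite(vals)]
            rows.append((gid, float(vals.mean()) if len(vals) else np.nan,
                         len(vals) == 0))
    return pd.DataFrame(rows, columns=["group_id", "log2_enrichment",
                                       "flagged"])


def boxplot_summary(records: pd.DataFrame, value: str = "relative",
                    by: str = "library_id") -> pd.DataFrame:
    """Median, quartiles, 1.5 x IQR whiskers and outlier counts per library,
    the conventions of a standard box plot."""
    rows = []
    for key, grp in records.groupby(by):
        vals = grp[value].dropna().to_numpy()
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_w = vals[vals >= q1 - 1.5 * iqr].min()
        hi_w = vals[vals <= q3 + 1.5 * iqr].max()
        n_out = int(((vals < lo_w) | (vals > hi_w)).sum())
        rows.append((key, med, q1, q3, lo_w, hi_w, n_out, len(vals)))
    return pd.DataFrame(rows, columns=[by, "median", "q1", "q3",
                                       "whisker_low", "whisker_high",
                                       "n_outliers", "n"])
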