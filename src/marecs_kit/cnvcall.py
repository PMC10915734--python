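"""Stage-one screening: whole-chromosome aneuploidy calls from shallow binned
read counts, reported as ISCN-like karyotype strings with sex masked as XN."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CNVConfig:
    gain_threshold: float = 1.35  # mean bin ratio at/above which a chromosome is a gain
    loss_threshold: float = 0.65
    min_bins: int = 20

    def __post_init__(self):
        if not self.loss_threshold < 1 < self.gain_threshold:
            raise ValueError("thresholds must satisfy loss < 1 < gain")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-bin ratios against the median bin count of putatively disomic
    chromosomes (outlier chromosomes are excluded iteratively, so a large
    trisomy cannot drag the baseline). Scale-invariant by construction.

    `counts` needs columns chrom, start, end, count; returns a copy with a
    `ratio` column added."""
    df = counts.copy()
    if (df["count"] < 0).any():
        raise ValueError("negative bin counts")
    total = df["count"].sum()
    if total == 0:
        raise ValueError("all-zero bin counts cannot be normalized")
    keep = set(df["chrom"].unique())
    for _ in range(3):
        med = df.loc[df["chrom"].isin(keep), "count"].median()
        if med == 0:
            break
        means = df.groupby("chrom")["count"].mean() / med
        new_keep = set(means[(means - 1).abs() <= 0.25].index)
        if not new_keep or new_keep == keep:
            keep = new_keep or keep
            break
        keep = new_keep
    med = df.loc[df["chrom"].isin(keep), "count"].median()
    if med == 0:
        med = df["count"].median() or 1.0
    df["ratio"] = df["count"] / med
    return df


def call_aneuploidy(ratios: pd.DataFrame, cfg: CNVConfig | None = None) -> dict[str, int | None]:
    """Copy state per chromosome: 3 if mean ratio >= gain, 1 if <= loss, else 2;
    chromosomes with fewer than min_bins bins are no-called (None)."""
    cfg = cfg or CNVConfig()
    states: dict[str, int | None] = {}
    for chrom, grp in ratios.groupby("chrom", sort=False):
        if len(grp) < cfg.min_bins:
            states[chrom] = None
            continue
        mean = grp["ratio"].mean()
        if mean >= cfg.gain_threshold:
            states[chrom] = 3
        elif mean <= cfg.loss_threshold:
            states[chrom] = 1
        else:
            states[chrom] = 2
    return states


def _chrom_sort_key(name: str):
    label = re.sub(r"^chr", "", name)
    return (0, int(label)) if label.isdigit() else (1, label)


def format_karyotype(
    states: dict[str, int | None], n_chrom_base: int = 46, times_glyph: str = "×"
) -> str:
    """ISCN-like string: euploid -> '46,XN'; each trisomy appends '+<chrom>(×3)'
    and bumps the modal number, each monosomy appends '-<chrom>(×1)' and lowers
    it. Sex is masked as XN; the minus is ASCII."""
    modal = n_chrom_base
    parts = []
    for chrom in sorted(states, key=_chrom_sort_key):
        state = states[chrom]
        label = re.sub(r"^chr", "", chrom)
        if state == 3:
            modal += 1
            parts.append(f"+{label}({times_glyph}3)")
        elif state == 1:
            modal -= 1
            parts.append(f"-{label}({times_glyph}1)")
    return ",".join([f"{modal}", "XN"] + parts)


def read_bincounts_tsv(path: str) -> dict[str, pd.DataFrame]:
    """Per-embryo bin-count frames from a TSV with columns
    embryo, chrom, start, end, count."""
    df = pd.read_csv(path, sep="\t")
    return {str(e): g.drop(columns="embryo").reset_index(drop=True) for e, g in df.groupby("embryo")}


def normalize_counts_cohort(
    counts_by_embryo: dict[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Cohort normalization: each bin's expected disomic count is its median
    across embryos (at any one locus most embryos are disomic), then each sample
    is rescaled so its modal ratio is 1. Resolves the baseline ambiguity that a
    within-sample median cannot when few chromosomes are present."""
    ids = list(counts_by_embryo)
    mat = np.stack([counts_by_embryo[e]["count"].to_numpy(float) for e in ids])
    ref = np.median(mat, axis=0)
    ref[ref == 0] = np.nan
    out = {}
    for i, e in enumerate(ids):
        ratio = mat[i] / ref
        df = counts_by_embryo[e].copy()
        df["ratio"] = np.nan_to_num(ratio, nan=1.0)
        # per-sample rescale: candidate scales are per-chromosome mean ratios;
        # choose the one that leaves the most chromosomes disomic, preferring
        # the gentlest rescale on ties (a bin-median baseline is already depth-
        # matched, so a sample-wide shift must earn its keep)
        chrom_means = df.groupby("chrom")["ratio"].mean()
        best = 1.0
        best_key = (-1, 0.0)
        for s in list(chrom_means) + [1.0]:
            if not s > 0:
                continue
            n_disomic = int(((chrom_means / s - 1).abs() <= 0.25).sum())
            key = (n_disomic, -abs(np.log(s)))
            if key > best_key:
                best_key, best = key, s
        df["ratio"] = df["ratio"] / best
        out[e] = df
    return out


def screen_embryos(
    counts_by_embryo: dict[str, pd.DataFrame],
    cfg: CNVConfig | None = None,
    cohort: bool | None = None,
):
    """Karyotype every embryo; returns {embryo: (karyotype string, states, ratios)}.

    With >= 3 embryos the cohort-median baseline is used by default; otherwise
    each sample is normalized against its own disomic median."""
    if cohort is None:
        cohort = len(counts_by_embryo) >= 3
    if cohort:
        normalized = normalize_counts_cohort(counts_by_embryo)
    else:
        normalized = {e: normalize_counts(df) for e, df in counts_by_embryo.items()}
    out = {}
    for embryo, ratios in normalized.items():
        states = call_aneuploidy(ratios, cfg)
        out[embryo] = (format_karyotype(states), states, ratios)
    return out
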