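"""Beta values, detection filtering, promoter probes, and delta-beta calls.

Beta = M / (M + U) from methylated and unmethylated probe intensities.
Entries whose fluorescence was not significantly above background
(detection p > 0.05) are masked, not zeroed. Promoter probes run from
1500 bp upstream of the TSS (in the transcription direction) through the
end of the first coding exon. A probe is called hypo-/hypermethylated
when |beta_KO - beta_control| strictly exceeds the cutoff (default 0.2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "beta_value",
    "beta_matrix",
    "filter_detection",
    "select_promoter_probes",
    "classify_dm",
    "delta_beta_table",
]


def beta_value(M, U):
    """M / (M + U); entries with M + U == 0 come back masked (NaN)."""
    M = np.asarray(M, float)
    U = np.asarray(U, float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be >= 0")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def _sample_names(table: pd.DataFrame) -> list[str]:
    return [c[2:] for c in table.columns if c.startswith("M_")]


def beta_matrix(table: pd.DataFrame, p_cut: float = 0.05) -> pd.DataFrame:
    """Probes x samples beta values from a probe table with M_/U_/detp_
    column triples; detection-filtered entries are NaN."""
    out = {}
    for s in _sample_names(table):
        beta = beta_value(table[f"M_{s}"], table[f"U_{s}"])
        detp = table[f"detp_{s}"].to_numpy(float)
        beta = np.where(detp > p_cut, np.nan, beta)
        out[s] = beta
    return pd.DataFrame(out, index=table["probe"])


def filter_detection(table: pd.DataFrame, p_cut: float = 0.05) -> pd.DataFrame:
    """Mask per-sample M/U entries whose detection p exceeds the cutoff
    (strictly greater; p == cutoff is retained)."""
    out = table.copy()
    for s in _sample_names(table):
        bad = out[f"detp_{s}"].to_numpy(float) > p_cut
        out.loc[bad, f"M_{s}"] = np.nan
        out.loc[bad, f"U_{s}"] = np.nan
    return out


def select_promoter_probes(table: pd.DataFrame, transcripts) -> pd.DataFrame:
    """Keep probes inside [TSS - 1500 (upstream), end of first coding exon]
    of any transcript. Transcripts without CDS are skipped and counted in
    ``DataFrame.attrs['skipped_transcripts']``."""
    windows: dict[str, list[tuple[int, int]]] = {}
    skipped = 0
    for t in transcripts:
        if not t.cds_exons:
            skipped += 1
            continue
        if t.strand == "+":
            lo, hi = t.tss - 1500, t.cds_exons[0].end - 1
        else:
            lo, hi = t.cds_exons[0].start, t.tss + 1500
        windows.setdefault(t.chrom, []).append((lo, hi))
    chrom = table["chrom"].to_numpy()
    pos = table["pos"].to_numpy(int)
    keep = np.zeros(len(table), bool)
    for c, wins in windows.items():
        sel = chrom == c
        if not sel.any():
            continue
        p = pos[sel]
        hit = np.zeros(len(p), bool)
        for lo, hi in wins:
            hit |= (p >= lo) & (p <= hi)
        keep[np.flatnonzero(sel)[hit]] = True
    out = table[keep].reset_index(drop=True)
    out.attrs["skipped_transcripts"] = skipped
    return out


def classify_dm(beta_control, beta_ko, cutoff: float = 0.2):
    """'hypomethylated' / 'hypermethylated' / 'unchanged' by the signed
    delta (KO - control); masked inputs come back 'unclassified'."""
    bc = np.asarray(beta_control, float)
    bk = np.asarray(beta_ko, float)
    delta = bk - bc
    out = np.where(
        np.isnan(delta), "unclassified",
        np.where(delta < -cutoff, "hypomethylated",
                 np.where(delta > cutoff, "hypermethylated", "unchanged")),
    )
    if out.ndim == 0:
        return str(out)
    return out


def delta_beta_table(table: pd.DataFrame, control_prefix: str = "wt",
                     ko_prefix: str = "dko", p_cut: float = 0.05,
                     cutoff: float = 0.2) -> pd.DataFrame:
    """Per-probe condition means (over unmasked replicate betas), delta,
    and the hypo/hyper call."""
    betas = beta_matrix(table, p_cut)
    ctrl_cols = [c for c in betas.columns if c.startswith(control_prefix)]
    ko_cols = [c for c in betas.columns if c.startswith(ko_prefix)]
    if not ctrl_cols or not ko_cols:
        raise ValueError("no samples matched the condition prefixes")
    bc = betas[ctrl_cols].mean(axis=1, skipna=True).to_numpy()
    bk = betas[ko_cols].mean(axis=1, skipna=True).to_numpy()
    return pd.DataFrame(
        {
            "chrom": table["chrom"].to_numpy(),
            "pos": table["pos"].to_numpy(),
            "beta_control": bc,
            "beta_ko": bk,
            "delta": bk - bc,
            "call": classify_dm(bc, bk, cutoff),
        },
        index=betas.index,
    )
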