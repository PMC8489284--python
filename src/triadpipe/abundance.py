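"""Protein-level reporter quantification and responsive-protein calling.

Peptide reporter intensities are rolled up to protein (locus) level by
summing over each protein's locus-unique peptides; proteins without
unique peptides are not quantified. The per-protein fold change is

    ratio = mean_i( NP_i / mean(CK) )

over treatment replicates, which recovers a planted fold change exactly
in the noise-free limit. Proteins are called phosphate-deficiency
responsive when the ratio clears the inclusive thresholds ≥1.20 (up)
or ≤0.83 (down); a two-sided pooled t-test on log abundances is always
computed and optionally gates the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import StatisticsError, ValidationError
from .mapping import PeptideMatch
from .simulate import ReplicateDesign
from . import stats as stats_core

REG_CLASSES = ("up", "down", "unchanged", "not_quantified")


@dataclass
class PdrpCallConfig:
    """Thresholds and gating for responsive-protein calling."""

    up_threshold: float = 1.20
    down_threshold: float = 0.83
    alpha: float = 0.05
    require_all_replicates: bool = True
    p_filter_enabled: bool = False

    def __post_init__(self):
        if not self.down_threshold < 1 < self.up_threshold:
            raise ValidationError("need down_threshold < 1 < up_threshold")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


def normalize_channels(
    table: pd.DataFrame,
    method: str = "total_sum",
    design: Optional[ReplicateDesign] = None,
) -> pd.DataFrame:
    """Equalise reporter channels by total sum or median scaling.

    Each channel is rescaled so channel totals (or medians) match their
    across-channel mean; within-channel structure is preserved.
    ``none`` is the identity.
    """
    if method == "none":
        return table.copy()
    design = design or ReplicateDesign()
    channels = design.channels
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise ValidationError(f"missing channels {missing}")
    values = table[channels].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("negative intensities")
    if method == "total_sum":
        stat = values.sum(axis=0)
    elif method == "median":
        stat = np.median(values, axis=0)
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    if (stat == 0).any():
        zero = [c for c, s in zip(channels, stat) if s == 0]
        raise ValidationError(f"channels with all-zero intensities: {zero}")
    out = table.copy()
    out[channels] = values * (stat.mean() / stat)
    return out


def quantify_proteins(
    table: pd.DataFrame,
    matches: Mapping[str, PeptideMatch],
    design: Optional[ReplicateDesign] = None,
    protein_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Roll peptide reporter areas up to protein level.

    Protein abundance per channel is the sum of reporter areas over the
    protein's locus-unique peptides (each peptide credited to the
    single locus it matches). Proteins with zero unique peptides are
    kept with NaN channels and ``quantified = False``.

    Returns a frame indexed by protein id with the channel columns,
    ``n_unique_peptides``, ``quantified``, ``ratio`` and ``p_value``.
    """
    design = design or ReplicateDesign()
    channels = design.channels
    unrecorded = [p for p in table["peptide"].unique() if p not in matches]
    if unrecorded:
        raise ValidationError(
            f"{len(unrecorded)} peptides lack a specificity record "
            f"(e.g. {unrecorded[0]!r})"
        )
    proteins = set(protein_ids) if protein_ids is not None else set(table["protein_id"])
    sums: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    for _, row in table.iterrows():
        match = matches[row["peptide"]]
        if not match.is_unique:
            continue
        (locus,) = match.loci
        proteins.add(locus)
        vec = row[channels].to_numpy(dtype=float)
        if locus in sums:
            sums[locus] += vec
            counts[locus] += 1
        else:
            sums[locus] = vec.copy()
            counts[locus] = 1

    n_ck = design.n_control
    records = []
    for pid in sorted(proteins):
        if pid in sums:
            abund = sums[pid]
            ck, np_ = abund[:n_ck], abund[n_ck:]
            ratio = float(np.mean(np_ / ck.mean()))
            if len(ck) >= 2 and len(np_) >= 2:
                _, _, p = stats_core.student_t(np.log(np_), np.log(ck), "pooled")
            else:
                p = float("nan")
            records.append([pid, *abund, counts[pid], True, ratio, p])
        else:
            records.append(
                [pid, *([np.nan] * len(channels)), 0, False, np.nan, np.nan]
            )
    out = pd.DataFrame(
        records,
        columns=["protein_id", *channels, "n_unique_peptides", "quantified", "ratio", "p_value"],
    ).set_index("protein_id")
    return out


def call_pdrps(
    quants: pd.DataFrame,
    cfg: Optional[PdrpCallConfig] = None,
    design: Optional[ReplicateDesign] = None,
) -> pd.DataFrame:
    """Classify quantified proteins as up / down / unchanged.

    Thresholds are inclusive (a ratio of exactly 1.20 is up, exactly
    0.83 is down). When ``p_filter_enabled``, the call additionally
    requires p < alpha. Proteins missing any required channel are
    ``not_quantified`` when ``require_all_replicates``.
    """
    cfg = cfg or PdrpCallConfig()
    design = design or ReplicateDesign()
    channels = design.channels
    if cfg.p_filter_enabled and (design.n_control < 2 or design.n_treatment < 2):
        raise StatisticsError("p-filter needs ≥2 replicates per condition")
    out = quants.copy()
    classes = []
    for _, row in out.iterrows():
        complete = bool(row["quantified"]) and np.isfinite(
            row[channels].to_numpy(dtype=float)
        ).all()
        if cfg.require_all_replicates and not complete:
            classes.append("not_quantified")
            continue
        if not bool(row["quantified"]):
            classes.append("not_quantified")
            continue
        ratio = row["ratio"]
        significant = (not cfg.p_filter_enabled) or (row["p_value"] < cfg.alpha)
        if ratio >= cfg.up_threshold and significant:
            classes.append("up")
        elif ratio <= cfg.down_threshold and significant:
            classes.append("down")
        else:
            classes.append("unchanged")
    out["reg_class"] = classes
    return out


@dataclass
class ConcordanceReport:
    """Direction/class agreement between two quantification runs."""

    n_shared: int
    n_concordant: int
    table: pd.DataFrame

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_shared if self.n_shared else float("nan")


def concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ConcordanceReport:
    """Per-protein agreement of two classified quant tables.

    A shared protein is concordant when its log-ratio sign and its
    regulation class agree in both runs (used here the way a targeted
    follow-up run validates a discovery run).
    """
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValidationError("no shared protein ids")
    rows = []
    for pid in shared:
        ra, rb = calls_a.loc[pid, "ratio"], calls_b.loc[pid, "ratio"]
        ca, cb = calls_a.loc[pid, "reg_class"], calls_b.loc[pid, "reg_class"]
        same_sign = np.sign(np.log(ra)) == np.sign(np.log(rb))
        ok = bool(same_sign and ca == cb)
        rows.append([pid, ra, rb, ca, cb, ok])
    table = pd.DataFrame(
        rows, columns=["protein_id", "ratio_a", "ratio_b", "class_a", "class_b", "concordant"]
    ).set_index("protein_id")
    return ConcordanceReport(len(shared), int(table["concordant"].sum()), table)


def volcano_coordinates(quants: pd.DataFrame) -> pd.DataFrame:
    """(log2 ratio, −log10 p) per quantified protein; p = 0 is clipped."""
    sub = quants[quants["quantified"]].copy()
    tiny = np.finfo(float).tiny
    return pd.DataFrame(
        {
            "log2_ratio": np.log2(sub["ratio"].to_numpy(dtype=float)),
            "neg_log10_p": -np.log10(
                np.clip(sub["p_value"].to_numpy(dtype=float), tiny, None)
            ),
        },
        index=sub.index,
    )
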