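"""qRT-PCR relative quantification and induced/repressed/unchanged calls.

Replicate Ct tables (target and reference-gene cycle thresholds per
gene, treatment and timepoint) are turned into relative quantities by
the standard comparative-Ct method:

    dCt(t)  = mean Ct_target(t) - mean Ct_reference(t)
    ddCt(t) = dCt(t) - dCt(0)          (timepoint 0 is the calibrator)
    RQ(t)   = 2 ** (-ddCt(t))

Replicates are averaged on the Ct scale before differencing (the common
practice); ``aggregate="per_replicate"`` instead computes per-replicate
RQs and takes their geometric mean.  A gene is called *induced* when any
post-treatment RQ reaches ``up_fold`` (default 2), *repressed* when any
RQ falls to ``down_fold`` (default 0.5), otherwise *unchanged*; if both
thresholds are crossed the larger |log2 RQ| wins, ties going to induced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_GENE",
    "TIMEPOINTS_H",
    "ResponseCall",
    "PanelSummary",
    "read_ct_table",
    "validate_ct_table",
    "relative_quantity",
    "call_response",
    "call_responses",
    "summarize_panel",
]

logger = logging.getLogger(__name__)

REFERENCE_GENE = "EF1γ"
TIMEPOINTS_H = (0, 9, 12, 24, 48)

CT_COLUMNS = ["gene", "treatment", "timepoint_h", "replicate", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class ResponseCall:
    gene: str
    treatment: str
    rq_by_timepoint: dict[int, float]
    call: str  # induced | repressed | unchanged
    trigger_timepoint: int | None = None


@dataclass(frozen=True)
class PanelSummary:
    n_assayed: int
    per_treatment: dict[str, dict[str, int]]  # treatment -> {induced, repressed, unchanged}
    n_both_induced: int
    genes_by_category: dict[str, dict[str, tuple[str, ...]]]
    both_induced_genes: tuple[str, ...]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns gene, treatment, timepoint_h, replicate,
    ct_target, ct_reference and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    df["timepoint_h"] = df["timepoint_h"].astype(int)
    validate_ct_table(df)
    return df


def validate_ct_table(df: pd.DataFrame) -> None:
    for col in ("ct_target", "ct_reference"):
        bad = df[(df[col] <= 0) | (df[col] >= 45)]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValueError(
                f"{col} out of range (0, 45) for gene {row['gene']!r} "
                f"treatment {row['treatment']!r} t={row['timepoint_h']}"
            )
    for (gene, treatment), grp in df.groupby(["gene", "treatment"], sort=False):
        if 0 not in set(grp["timepoint_h"]):
            raise ValueError(f"missing calibrator (t=0) for gene {gene!r}, treatment {treatment!r}")


def relative_quantity(
    df: pd.DataFrame,
    *,
    aggregate: str = "ct_mean",
    normalize_by_control: bool = False,
    control_treatment: str = "control",
) -> pd.DataFrame:
    """Relative quantities per (gene, treatment, timepoint).

    Returns a frame with columns gene, treatment, timepoint_h, delta_ct,
    rq.  RQ at the calibrator timepoint is exactly 1.  With
    ``normalize_by_control`` the RQ of ``control_treatment`` at the same
    timepoint divides the treated RQ (mock-treatment correction).
    """
    validate_ct_table(df)
    if aggregate not in ("ct_mean", "per_replicate"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    rows = []
    for (gene, treatment), grp in df.groupby(["gene", "treatment"], sort=False):
        if aggregate == "ct_mean":
            per_t = grp.groupby("timepoint_h").agg(
                ct_t=("ct_target", "mean"), ct_r=("ct_reference", "mean")
            )
            dct = per_t["ct_t"] - per_t["ct_r"]
            dct0 = dct.loc[0]
            for t, d in dct.items():
                rq = 1.0 if t == 0 else 2.0 ** (-(d - dct0))
                rows.append((gene, treatment, int(t), float(d), float(rq)))
        else:
            per_rep = grp.set_index(["timepoint_h", "replicate"])
            dct = per_rep["ct_target"] - per_rep["ct_reference"]
            dct0 = dct.loc[0].mean()
            for t in sorted(grp["timepoint_h"].unique()):
                if t == 0:
                    rows.append((gene, treatment, 0, float(dct0), 1.0))
                    continue
                rqs = 2.0 ** (-(dct.loc[t] - dct0))
                geo = float(np.exp(np.mean(np.log(rqs))))
                rows.append((gene, treatment, int(t), float(dct.loc[t].mean()), geo))
    out = pd.DataFrame(rows, columns=["gene", "treatment", "timepoint_h", "delta_ct", "rq"])

    if normalize_by_control:
        ctrl = out[out["treatment"] == control_treatment].set_index(["gene", "timepoint_h"])["rq"]
        treated = out["treatment"] != control_treatment

        def norm(row):
            key = (row["gene"], row["timepoint_h"])
            if key in ctrl.index:
                return row["rq"] / ctrl.loc[key]
            return row["rq"]

        out.loc[treated, "rq"] = out.loc[treated].apply(norm, axis=1)
    return out


def call_response(
    rq_by_timepoint: dict[int, float],
    up_fold: float = 2.0,
    down_fold: float = 0.5,
) -> tuple[str, int | None]:
    """Three-way call from post-treatment RQs; returns (call, trigger t).

    Induced if any RQ >= ``up_fold``; else repressed if any RQ <=
    ``down_fold``; if both thresholds are crossed the timepoint with the
    larger |log2 RQ| decides, a tie going to induced.
    """
    post = {t: rq for t, rq in rq_by_timepoint.items() if t > 0}
    if not post:
        return "unchanged", None
    for t, rq in post.items():
        if rq <= 0:
            raise ValueError(f"nonpositive RQ {rq} at t={t}")
    up_hits = {t: rq for t, rq in post.items() if rq >= up_fold}
    down_hits = {t: rq for t, rq in post.items() if rq <= down_fold}
    if up_hits and down_hits:
        t_up, rq_up = max(up_hits.items(), key=lambda kv: abs(math.log2(kv[1])))
        t_dn, rq_dn = max(down_hits.items(), key=lambda kv: abs(math.log2(kv[1])))
        if abs(math.log2(rq_up)) >= abs(math.log2(rq_dn)):
            return "induced", t_up
        return "repressed", t_dn
    if up_hits:
        t_up = max(up_hits, key=lambda t: up_hits[t])
        return "induced", t_up
    if down_hits:
        t_dn = min(down_hits, key=lambda t: down_hits[t])
        return "repressed", t_dn
    return "unchanged", None


def call_responses(
    rq_df: pd.DataFrame,
    up_fold: float = 2.0,
    down_fold: float = 0.5,
) -> list[ResponseCall]:
    """One ResponseCall per (gene, treatment) in a relative_quantity frame."""
    calls = []
    for (gene, treatment), grp in rq_df.groupby(["gene", "treatment"], sort=False):
        rq = {int(t): float(r) for t, r in zip(grp["timepoint_h"], grp["rq"])}
        call, trigger = call_response(rq, up_fold, down_fold)
        calls.append(ResponseCall(gene, treatment, rq, call, trigger))
    return calls


def summarize_panel(
    calls_pathogen: list[ResponseCall],
    calls_sa: list[ResponseCall],
    panel: list[str],
) -> PanelSummary:
    """Category counts per treatment and the induced-set intersection.

    Genes of the panel with calls under only one treatment are counted in
    that treatment's categories but excluded from the intersection (and
    logged).  All arithmetic is exact set algebra over the panel.
    """
    panel_set = list(dict.fromkeys(panel))  # preserve order, drop dups
    by_treatment: dict[str, dict[str, str]] = {}
    for name, calls in (("pathogen", calls_pathogen), ("SA", calls_sa)):
        mapping = {}
        for c in calls:
            if c.gene in panel_set:
                mapping[c.gene] = c.call
        by_treatment[name] = mapping

    per_treatment = {}
    genes_by_category = {}
    for name, mapping in by_treatment.items():
        cats = {"induced": [], "repressed": [], "unchanged": []}
        for gene in panel_set:
            if gene in mapping:
                cats[mapping[gene]].append(gene)
        per_treatment[name] = {k: len(v) for k, v in cats.items()}
        genes_by_category[name] = {k: tuple(v) for k, v in cats.items()}

    covered_both = [
        g for g in panel_set if g in by_treatment["pathogen"] and g in by_treatment["SA"]
    ]
    only_one = [
        g
        for g in panel_set
        if (g in by_treatment["pathogen"]) != (g in by_treatment["SA"])
    ]
    if only_one:
        logger.warning(
            "genes with calls under only one treatment excluded from intersection: %s",
            ", ".join(only_one),
        )
    both_induced = tuple(
        g
        for g in covered_both
        if by_treatment["pathogen"][g] == "induced" and by_treatment["SA"][g] == "induced"
    )
    return PanelSummary(
        n_assayed=len(panel_set),
        per_treatment=per_treatment,
        n_both_induced=len(both_induced),
        genes_by_category=genes_by_category,
        both_induced_genes=both_induced,
    )
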