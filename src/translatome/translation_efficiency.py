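"""Translation efficiency: per-gene TE, differential TE, class comparisons.

Translation efficiency (TE) of a gene is the ratio of its ribosome-bound
mRNA abundance to its total mRNA abundance, computed here as
``(ribo_tpm + pc) / (rna_tpm + pc)`` with a symmetric pseudocount ``pc``
(default 0.5 TPM) that bounds TE for genes undetected in one assay.
log2(TE) is the working scale throughout.

Differential TE between two cell types is a Welch two-sample t-test on the
per-replicate log2 TE values (Ribo-Seq and RNA-seq replicates are paired by
replicate index within each cell type), with Benjamini-Hochberg adjustment
across all tested genes. This is a deliberately simple, fully specified
statistic: every quantity entering it is defined above, so results are
reproducible from the TPM matrix alone.

Class-level comparisons (e.g. TOP mRNAs vs all other genes) use a two-sided
Mann-Whitney U test on log2(TE), exact for small groups and the tie-corrected
normal approximation otherwise, and report the mean log2(TE) of class and
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, ValidationError
from .quantify import ConditionTPM, TPMMatrix

logger = logging.getLogger("translatome")

DEFAULT_PSEUDOCOUNT = 0.5

_TE_COLUMNS = ["gene_id", "cell_type", "ribo_mean_tpm", "rna_mean_tpm", "te", "log2_te", "defined"]


@dataclass(frozen=True)
class TETable:
    """Long-format per-gene TE table: one row per (gene, cell type).

    ``defined`` marks rows whose log2(TE) is finite; undefined rows (zero
    denominator or zero ratio at pseudocount 0) are excluded from all
    downstream statistics.
    """

    table: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        missing = [c for c in _TE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"TE table missing columns {missing}")

    def for_cell(self, cell_type: str) -> pd.DataFrame:
        sub = self.table[self.table["cell_type"] == cell_type]
        if sub.empty:
            raise ValidationError(f"no TE rows for cell type {cell_type!r}")
        return sub

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def to_frame(self) -> pd.DataFrame:
        return (
            self.table[_TE_COLUMNS]
            .sort_values(["cell_type", "gene_id"])
            .reset_index(drop=True)
        )


def concat_te(tables: Sequence[TETable]) -> TETable:
    """Stack single-cell TE tables into one long table."""
    if not tables:
        raise ValidationError("nothing to concatenate")
    pcs = {t.pseudocount for t in tables}
    if len(pcs) > 1:
        raise ValidationError(f"mixed pseudocounts {sorted(pcs)}")
    return TETable(
        table=pd.concat([t.table for t in tables], ignore_index=True),
        pseudocount=tables[0].pseudocount,
    )


def compute_te(
    ribo: ConditionTPM, rna: ConditionTPM, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> TETable:
    """Per-gene TE and log2(TE) for one cell type.

    Both inputs must cover the same gene universe and cell type. With
    ``pseudocount`` 0, genes with zero RNA (or zero ribo) TPM get an
    undefined log2(TE) and are flagged ``defined=False``.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if ribo.cell_type != rna.cell_type:
        raise ValidationError(
            f"cell type mismatch: ribo {ribo.cell_type!r} vs rna {rna.cell_type!r}"
        )
    if not ribo.mean_tpm.index.equals(rna.mean_tpm.index):
        diff = set(ribo.mean_tpm.index) ^ set(rna.mean_tpm.index)
        first = sorted(diff)[0] if diff else "(ordering differs)"
        raise ValidationError(f"gene universes differ; first discrepancy: {first}")
    r = ribo.mean_tpm.to_numpy(dtype=float)
    m = rna.mean_tpm.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = (r + pseudocount) / (m + pseudocount)
        log2_te = np.log2(te)
    defined = np.isfinite(log2_te)
    if (~defined).any():
        logger.warning(
            "%d genes have undefined TE in %s (pseudocount=%g)",
            int((~defined).sum()),
            ribo.cell_type,
            pseudocount,
        )
    table = pd.DataFrame(
        {
            "gene_id": ribo.mean_tpm.index,
            "cell_type": ribo.cell_type,
            "ribo_mean_tpm": r,
            "rna_mean_tpm": m,
            "te": te,
            "log2_te": log2_te,
            "defined": defined,
        }
    )
    return TETable(table=table, pseudocount=float(pseudocount))


@dataclass(frozen=True)
class DiffTEResult:
    """Per-gene differential TE between two cell types (A minus B)."""

    cell_a: str
    cell_b: str
    table: pd.DataFrame  # gene_id, delta_log2_te, t_statistic, p_value, q_value

    def to_frame(self) -> pd.DataFrame:
        return self.table.sort_values("gene_id").reset_index(drop=True)


def _replicate_log2_te(
    tpm: TPMMatrix, cell: str, pseudocount: float
) -> np.ndarray:
    """Genes x replicates matrix of log2((ribo+pc)/(rna+pc)) for one cell."""
    ribo = tpm.samples.replicates(cell, "ribo")
    rna = tpm.samples.replicates(cell, "rna")
    if len(ribo) < 2 or len(rna) < 2:
        raise ValidationError(f"cell {cell!r} needs >= 2 ribo and >= 2 rna replicates")
    if set(ribo) != set(rna):
        raise ValidationError(
            f"cell {cell!r} has unpaired replicate indices: "
            f"ribo {sorted(ribo)} vs rna {sorted(rna)}"
        )
    reps = sorted(ribo)
    r = tpm.tpm[[ribo[i] for i in reps]].to_numpy(dtype=float)
    m = tpm.tpm[[rna[i] for i in reps]].to_numpy(dtype=float)
    return np.log2((r + pseudocount) / (m + pseudocount))


def differential_te(
    tpm: TPMMatrix,
    cell_a: str,
    cell_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_mean_tpm: float = 1.0,
) -> DiffTEResult:
    """Welch t-test on per-replicate log2 TE between two cell types.

    Ribo/RNA replicates are paired by replicate index within each cell type.
    Genes whose mean TPM stays below ``min_mean_tpm`` in every involved
    (cell, assay) condition are excluded before testing; BH q-values are
    computed over the tested genes only.
    """
    if pseudocount <= 0:
        raise ValidationError("differential TE needs a positive pseudocount")
    la = _replicate_log2_te(tpm, cell_a, pseudocount)
    lb = _replicate_log2_te(tpm, cell_b, pseudocount)

    means = []
    for cell in (cell_a, cell_b):
        for assay in ("ribo", "rna"):
            cols = tpm.samples.select(cell_type=cell, assay=assay)
            means.append(tpm.tpm[cols].mean(axis=1).to_numpy())
    expressed = (np.vstack(means) >= min_mean_tpm).any(axis=0)
    if not expressed.any():
        raise ValidationError("no gene passes the expression filter")

    la, lb = la[expressed], lb[expressed]
    genes = np.asarray(tpm.gene_ids)[expressed]

    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups with equal means -> 0/0; define t=0, p=1
    degenerate = ~np.isfinite(t) & np.isclose(la.mean(1), lb.mean(1))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "delta_log2_te": la.mean(1) - lb.mean(1),
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
        }
    )
    return DiffTEResult(cell_a=cell_a, cell_b=cell_b, table=table)


@dataclass(frozen=True)
class ClassComparison:
    """Mann-Whitney comparison of a gene class's log2(TE) vs the background."""

    class_name: str
    cell_type: str
    n_class: int
    n_background: int
    mean_log2_te_class: float
    mean_log2_te_background: float
    u_statistic: float
    p_value: float

    @property
    def mean_difference(self) -> float:
        return self.mean_log2_te_class - self.mean_log2_te_background

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class_name": self.class_name,
                    "cell_type": self.cell_type,
                    "n_class": self.n_class,
                    "n_background": self.n_background,
                    "mean_log2_te_class": self.mean_log2_te_class,
                    "mean_log2_te_background": self.mean_log2_te_background,
                    "mean_difference": self.mean_difference,
                    "u_statistic": self.u_statistic,
                    "p_value": self.p_value,
                }
            ]
        )


def class_te_comparison(
    te: TETable, class_set: Iterable[str], cell_type: str, class_name: str = "class"
) -> ClassComparison:
    """Compare log2(TE) of a gene class against all other defined genes.

    Two-sided Mann-Whitney U: exact enumeration when either group has fewer
    than 8 members, tie-corrected normal approximation otherwise.
    """
    sub = te.for_cell(cell_type)
    sub = sub[sub["defined"]]
    members = set(class_set)
    in_class = sub["gene_id"].isin(members).to_numpy()
    cls = sub.loc[in_class, "log2_te"].to_numpy()
    bg = sub.loc[~in_class, "log2_te"].to_numpy()
    if cls.size == 0:
        raise ValidationError(
            f"class {class_name!r} has no member with defined TE in {cell_type!r}"
        )
    if bg.size == 0:
        raise ValidationError(f"class {class_name!r} covers every gene; no background")
    method = "exact" if min(cls.size, bg.size) < 8 else "asymptotic"
    u, p = stats.mannwhitneyu(cls, bg, alternative="two-sided", method=method)
    return ClassComparison(
        class_name=class_name,
        cell_type=cell_type,
        n_class=int(cls.size),
        n_background=int(bg.size),
        mean_log2_te_class=float(cls.mean()),
        mean_log2_te_background=float(bg.mean()),
        u_statistic=float(u),
        p_value=float(min(p, 1.0)),
    )


@dataclass(frozen=True)
class AbundanceRanking:
    """Dense descending abundance ranking of one condition, with set flags."""

    condition: str
    table: pd.DataFrame  # gene_id, mean_tpm, rank, in_<set>...

    def to_frame(self) -> pd.DataFrame:
        return self.table.sort_values(["rank", "gene_id"]).reset_index(drop=True)


def rank_abundance(
    cond: ConditionTPM, highlight_sets: GeneSetCollection | None = None
) -> AbundanceRanking:
    """Rank genes by mean TPM, densely (ties share a rank, 1 = most abundant)."""
    if len(cond.mean_tpm) == 0:
        raise ValidationError("cannot rank an empty condition")
    tpm = cond.mean_tpm
    rank = tpm.rank(method="dense", ascending=False).astype(int)
    table = pd.DataFrame(
        {"gene_id": tpm.index, "mean_tpm": tpm.to_numpy(), "rank": rank.to_numpy()}
    )
    if highlight_sets is not None:
        for gs in highlight_sets:
            table[f"in_{gs.name}"] = table["gene_id"].isin(set(gs.members))
    return AbundanceRanking(condition=cond.label, table=table)
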