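"""Stage-wise, mouse-blocked Spearman screen for Nanog/Sox2 co-regulated genes.

Single-cell expression from gastrulation-stage epiblast is screened, one
embryonic stage at a time, for genes whose expression correlates with *Nanog*
and anticorrelates with *Sox2* (candidate Nanog-co-regulated genes), or the
converse (Sox2-co-regulated). Cells from the same mouse are correlated and
must not be pooled naively, so ranks are formed within mouse-of-origin blocks
and per-block Spearman coefficients are combined with weights ``n_b - 1``.
P-values come from within-block permutations; Benjamini–Hochberg correction
is applied per (stage, anchor) stratum across genes, and a gene must satisfy
both anchor conditions in the same stage, at >= ``min_stages`` stages, to be
called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "GeneScreenResult",
    "blocked_spearman",
    "bh_adjust",
    "correlated_gene_screen",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes expression with per-cell stage and mouse-of-origin labels."""

    values: np.ndarray
    gene_names: list[str]
    cell_stage: np.ndarray
    cell_mouse: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_stage = np.asarray(self.cell_stage)
        self.cell_mouse = np.asarray(self.cell_mouse)
        n, g = self.values.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{g} expression columns but {len(self.gene_names)} gene names")
        if len(self.cell_stage) != n or len(self.cell_mouse) != n:
            raise ValueError("stage/mouse labels must match the number of cells")

    @property
    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.cell_stage:
            seen.setdefault(str(s), None)
        return list(seen)

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_names)
        df.insert(0, "stage", self.cell_stage)
        df.insert(1, "mouse", self.cell_mouse)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        genes = [c for c in df.columns if c not in ("stage", "mouse")]
        return cls(
            values=df[genes].to_numpy(dtype=float),
            gene_names=genes,
            cell_stage=df["stage"].to_numpy(),
            cell_mouse=df["mouse"].to_numpy(),
        )


@dataclass
class GeneScreenResult:
    """Called gene sets plus the full per-(gene, stage, anchor) evidence table."""

    nanog_correlated: list[str]
    sox2_correlated: list[str]
    evidence: pd.DataFrame


MIN_BLOCK = 4  # blocks smaller than this carry no usable rank information


def _block_rank_normalise(v: np.ndarray, starts: list[np.ndarray]) -> np.ndarray:
    """Within-block average ranks, centred and scaled to unit norm per block.

    A block in which ``v`` is constant contributes a zero vector (and hence
    zero correlation for that block).
    """
    out = np.zeros_like(v, dtype=float)
    for idx in starts:
        r = rankdata(v[idx])
        r = r - r.mean()
        norm = np.sqrt(np.dot(r, r))
        if norm > 0:
            out[idx] = r / norm
    return out


def blocked_spearman(
    x: Sequence[float],
    y: Sequence[float],
    blocks: Sequence,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Spearman correlation combined across blocks, with a permutation p-value.

    Per-block coefficients (on within-block average ranks, ties averaged) are
    combined as ``rho = sum (n_b - 1) rho_b / sum (n_b - 1)``; blocks with
    fewer than 4 observations, or in which either variable is constant, are
    excluded. The two-sided p-value permutes ``y`` within blocks
    (``(1 + #{|rho_perm| >= |rho|}) / (n_perm + 1)``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    blocks = np.asarray(blocks)
    if not (len(x) == len(y) == len(blocks)):
        raise ValueError("x, y and blocks must have equal length")
    groups = []
    for b in pd.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        if len(idx) >= MIN_BLOCK and np.ptp(x[idx]) > 0 and np.ptp(y[idx]) > 0:
            groups.append(idx)
    if not groups:
        raise ValueError("no usable block (need >= 4 observations and variation in x and y)")
    weights = np.array([len(idx) - 1 for idx in groups], dtype=float)
    wsum = weights.sum()
    rho = 0.0
    xt = [_rank_unit(x[idx]) for idx in groups]
    yt = [_rank_unit(y[idx]) for idx in groups]
    for w, a, b in zip(weights, xt, yt):
        rho += w * float(np.dot(a, b))
    rho /= wsum
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        r = 0.0
        for w, a, b in zip(weights, xt, yt):
            r += w * float(np.dot(a, rng.permutation(b)))
        if abs(r / wsum) >= abs(rho) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return float(np.clip(rho, -1.0, 1.0)), float(p)


def _rank_unit(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    r = r - r.mean()
    norm = np.sqrt(np.dot(r, r))
    return r / norm if norm > 0 else r


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_(j >= i) m * p_(j) / j``, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _screen_stage_anchor(
    values: np.ndarray,
    anchor_col: int,
    gene_cols: np.ndarray,
    block_groups: list[np.ndarray],
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Blocked Spearman of every gene vs one anchor, vectorised over genes.

    The anchor is rank-normalised within blocks, weighted by ``(n_b - 1)/W``;
    gene columns are rank-normalised within blocks; rho is then a single
    matrix-vector product. The permutation null permutes the anchor within
    blocks, shared across genes, which is valid per gene under independence
    and lets all null correlations come from one matrix product.
    """
    weights = np.array([len(idx) - 1 for idx in block_groups], dtype=float)
    wsum = weights.sum()
    anchor = values[:, anchor_col]
    a_unit = _block_rank_normalise(anchor, block_groups)
    a_w = a_unit.copy()
    for w, idx in zip(weights, block_groups):
        a_w[idx] *= w / wsum

    genes_unit = np.empty((values.shape[0], len(gene_cols)))
    for j, g in enumerate(gene_cols):
        genes_unit[:, j] = _block_rank_normalise(values[:, g], block_groups)

    rho = genes_unit.T @ a_w

    perm_matrix = np.empty((values.shape[0], n_perm))
    for t in range(n_perm):
        col = a_w.copy()
        for idx in block_groups:
            col[idx] = col[idx][rng.permutation(len(idx))]
        perm_matrix[:, t] = col
    null = genes_unit.T @ perm_matrix  # genes x perms
    exceed = (np.abs(null) >= np.abs(rho)[:, None] - 1e-12).sum(axis=1)
    p = (1 + exceed) / (n_perm + 1)
    return rho, p


def correlated_gene_screen(
    expr: ExpressionMatrix,
    anchors: tuple[str, str] = ("Nanog", "Sox2"),
    alpha: float = 0.05,
    min_stages: int = 2,
    n_perm: int = 1000,
    seed: int | None = None,
    same_stage: bool = True,
    global_correction: bool = False,
) -> GeneScreenResult:
    """Screen all genes for correlation with Nanog and anticorrelation with Sox2.

    Per stage and per anchor, every non-anchor gene's blocked Spearman rho and
    permutation p-value against the anchor are computed; BH correction is
    applied across genes within each (stage, anchor) stratum (or globally with
    ``global_correction=True``). A gene is called Nanog-correlated if, in at
    least ``min_stages`` stages, it is significant (q < alpha) with rho > 0 vs
    Nanog and significant with rho < 0 vs Sox2 (in the same stage unless
    ``same_stage=False``); Sox2-correlated genes satisfy the mirrored rule.
    """
    nanog, sox2 = anchors
    anchor_cols = {a: expr.gene_index(a) for a in anchors}
    stages = expr.stages
    if len(stages) < 2:
        raise ValueError("screen needs at least 2 stages")
    gene_cols = np.array(
        [i for i, g in enumerate(expr.gene_names) if g not in anchors], dtype=int
    )
    gene_names = [expr.gene_names[i] for i in gene_cols]
    rng = np.random.default_rng(seed)

    rows = []
    for stage in stages:
        in_stage = np.flatnonzero(expr.cell_stage.astype(str) == stage)
        sub = expr.values[in_stage]
        mice = expr.cell_mouse[in_stage]
        block_groups = [
            idx
            for b in pd.unique(mice)
            if len(idx := np.flatnonzero(mice == b)) >= MIN_BLOCK
        ]
        if not block_groups:
            warnings.warn(f"stage {stage}: no mouse block with >= {MIN_BLOCK} cells; skipped")
            continue
        for anchor in anchors:
            ac = anchor_cols[anchor]
            if all(np.ptp(sub[idx, ac]) == 0 for idx in block_groups):
                warnings.warn(f"stage {stage}: anchor {anchor} constant; stage skipped")
                continue
            rho, p = _screen_stage_anchor(sub, ac, gene_cols, block_groups, n_perm, rng)
            for g, r_, p_ in zip(gene_names, rho, p):
                rows.append({"gene": g, "stage": stage, "anchor": anchor, "rho": r_, "p": p_})

    evidence = pd.DataFrame(rows)
    if evidence.empty:
        return GeneScreenResult([], [], evidence)
    if global_correction:
        evidence["q"] = bh_adjust(evidence["p"].to_numpy())
    else:
        evidence["q"] = np.nan
        for (_, _), idx in evidence.groupby(["stage", "anchor"]).groups.items():
            evidence.loc[idx, "q"] = bh_adjust(evidence.loc[idx, "p"].to_numpy())

    sig = evidence.assign(
        pos=lambda d: (d["q"] < alpha) & (d["rho"] > 0),
        neg=lambda d: (d["q"] < alpha) & (d["rho"] < 0),
    )
    piv_pos = sig.pivot_table(index="gene", columns=["stage", "anchor"], values="pos", aggfunc="any")
    piv_neg = sig.pivot_table(index="gene", columns=["stage", "anchor"], values="neg", aggfunc="any")

    def count_stages(gene: str, first_rule: str, second_rule: str) -> int:
        hits = 0
        indep = [0, 0]
        for stage in stages:
            try:
                a = bool(piv_pos.loc[gene, (stage, nanog)] if first_rule == "pos" else piv_neg.loc[gene, (stage, nanog)])
                b = bool(piv_neg.loc[gene, (stage, sox2)] if second_rule == "neg" else piv_pos.loc[gene, (stage, sox2)])
            except KeyError:
                continue
            hits += a and b
            indep[0] += a
            indep[1] += b
        return hits if same_stage else min(indep)

    genes_seen = piv_pos.index if not piv_pos.empty else []
    nanog_set = [g for g in genes_seen if count_stages(g, "pos", "neg") >= min_stages]
    sox2_set = [g for g in genes_seen if count_stages(g, "neg", "pos") >= min_stages]
    both = set(nanog_set) & set(sox2_set)
    if both:
        # opposite-signed significance across different stages; ambiguous, call neither
        warnings.warn(f"{len(both)} genes matched both rules; excluded from both sets")
        nanog_set = [g for g in nanog_set if g not in both]
        sox2_set = [g for g in sox2_set if g not in both]
    return GeneScreenResult(nanog_correlated=nanog_set, sox2_correlated=sox2_set, evidence=evidence)
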