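"""Synthetic embryos, explant assays and expression matrices with known truth.

Every downstream stage of the package is exercised on data from these
generators, which plant a recoverable ground truth:

- :func:`gen_embryo_stack` builds a multi-channel 3D stack of non-overlapping
  ellipsoidal nuclei whose NANOG and SOX2 levels follow opposing logistic
  gradients along the anterior–posterior axis, imaged through per-channel
  exponential depth attenuation plus additive Gaussian noise.
- :func:`gen_explant_assay` builds per-region SOX2 ANI samples and explant
  colony outcomes in which the colony reactivation rate equals the fraction
  of the colony's cells above a planted SOX2 threshold τ*.
- :func:`gen_expression_matrix` builds a cells x genes matrix over embryonic
  stages with mouse-of-origin structure, anchor genes (*Nanog* up, *Sox2*
  down) tied to a latent anterior–posterior score, planted correlated genes,
  independent null genes, and mouse-level random intercepts.

All generators are pure functions of their config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from epiquant.genescreen import ExpressionMatrix
from epiquant.imaging import ChannelMeta, ImageStack
from epiquant.quantify import score_colonies
from epiquant.thresholdscan import RegionAssay

__all__ = [
    "ExpressionModel",
    "EmbryoSimConfig",
    "NucleusTruth",
    "AssaySimConfig",
    "ExprSimConfig",
    "gen_embryo_stack",
    "gen_explant_assay",
    "gen_expression_matrix",
]

# per-channel attenuation constants typical of cleared-embryo confocal stacks
DEFAULT_CHANNELS = (("DAPI", 0.014), ("NANOG", 0.001), ("SOX2", 0.009))


@dataclass(frozen=True)
class ExpressionModel:
    """Opposing logistic gradients along the AP axis.

    At AP fraction ``a``, SOX2 = s_max * sigmoid(-(a - x0)/w) and
    NANOG = n_max * sigmoid((a - x0)/w); DAPI is constant. ``x0`` is the
    cross-over point (fraction of AP extent), ``w`` the transition width.
    """

    x0: float = 0.5
    w: float = 0.1
    s_max: float = 1000.0
    n_max: float = 1000.0
    dapi: float = 1000.0


@dataclass(frozen=True)
class EmbryoSimConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nuclei: int = 50
    nucleus_radius_um: tuple[float, float] = (3.0, 5.0)
    ap_axis: int = 2
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    noise_sd: float = 0.0
    channels: tuple[tuple[str, float], ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 8")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        rmin, rmax = self.nucleus_radius_um
        if not 0 < rmin <= rmax:
            raise ValueError("nucleus radii must be positive and min <= max")
        half_extent = min(s * sp for s, sp in zip(self.grid_shape, self.voxel_spacing_um)) / 2
        if rmax >= half_extent:
            raise ValueError("max nucleus radius must be smaller than half the shortest axis")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ap_axis not in (0, 1, 2):
            raise ValueError("ap_axis must be 0, 1 or 2")


@dataclass
class NucleusTruth:
    """Planted nucleus: position, geometry, and pre-attenuation intensities."""

    nucleus_id: int
    centroid: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    ap_fraction: float
    true_intensity: dict[str, float]


def gen_embryo_stack(cfg: EmbryoSimConfig) -> tuple[ImageStack, list[NucleusTruth]]:
    """Simulate a multi-channel embryo stack with planted nuclei.

    Nuclei are solid non-overlapping ellipsoids (axis ratios in [1, 1.5]);
    the recorded voxel value is ``true * exp(-k * depth_um) + noise``, with
    depth measured from the first z-plane. Raises if the requested density
    cannot be placed within bounded retries (the error names the achieved
    count). Deterministic given the config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.grid_shape
    spacing = np.asarray(cfg.voxel_spacing_um)
    rmin, rmax = cfg.nucleus_radius_um

    centres = []
    semi_axes = []
    max_tries = 200 * cfg.n_nuclei
    tries = 0
    while len(centres) < cfg.n_nuclei:
        if tries >= max_tries:
            raise RuntimeError(
                f"could only place {len(centres)} of {cfg.n_nuclei} nuclei after "
                f"{max_tries} tries; reduce n_nuclei or nucleus radius"
            )
        tries += 1
        r = rng.uniform(rmin, rmax)
        axes = r * rng.uniform(1.0, 1.5, size=3)
        margin_vox = axes / spacing + 1
        c = np.array([
            rng.uniform(m, s - 1 - m) if s - 1 - m > m else (s - 1) / 2
            for s, m in zip(shape, margin_vox)
        ])
        ok = True
        for c2, a2 in zip(centres, semi_axes):
            d = np.linalg.norm((c - c2) * spacing)
            if d <= axes.max() + a2.max():
                ok = False
                break
        if ok:
            centres.append(c)
            semi_axes.append(axes)

    em = cfg.expression_model
    channels = [ChannelMeta(name=n, k=k) for n, k in cfg.channels]
    data = np.zeros((len(channels), *shape), dtype=float)
    truths: list[NucleusTruth] = []
    extent = shape[cfg.ap_axis] - 1
    for i, (c, axes) in enumerate(zip(centres, semi_axes), start=1):
        a = float(c[cfg.ap_axis]) / extent
        intensity = {
            "DAPI": em.dapi,
            "SOX2": em.s_max * float(expit(-(a - em.x0) / em.w)),
            "NANOG": em.n_max * float(expit((a - em.x0) / em.w)),
        }
        lo = np.maximum(np.floor(c - axes / spacing - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + axes / spacing + 2).astype(int), shape)
        grid = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        dist2 = sum(((g - cc) * sp / ax) ** 2 for g, cc, sp, ax in zip(grid, c, spacing, axes))
        mask = dist2 <= 1.0
        for ci, ch in enumerate(channels):
            val = intensity.get(ch.name, em.dapi)
            sub = data[ci, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            sub[mask] = val
        truths.append(
            NucleusTruth(
                nucleus_id=i,
                centroid=tuple(float(v) for v in c),
                semi_axes_um=tuple(float(v) for v in axes),
                ap_fraction=a,
                true_intensity=intensity,
            )
        )

    depth = np.arange(shape[0]) * spacing[0]
    for ci, ch in enumerate(channels):
        data[ci] *= np.exp(-ch.k * depth)[:, None, None]
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    stack = ImageStack(data=data, channels=channels, voxel_spacing_um=tuple(cfg.voxel_spacing_um))
    return stack, truths


@dataclass(frozen=True)
class AssaySimConfig:
    """Explant-assay generator: regions with graded SOX2 and a planted τ*.

    Colony reactivation follows an identity link: a colony of
    ``cells_per_colony`` cells drawn from its region's ANI distribution has
    foci count Binomial(cells_per_colony, fraction of those cells above τ*).
    ``flat_rate`` replaces that rate with a constant (threshold-independent
    outcomes, for null calibration).
    """

    n_regions: int = 10
    cells_per_region: int = 200
    region_ani_means: tuple[float, ...] | None = None
    ani_sd: float = 10.0
    tau_star: float = 46.6
    colonies_per_region: int = 40
    cells_per_colony: int = 15
    flat_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("threshold scanning needs >= 3 regions")
        if min(self.cells_per_region, self.colonies_per_region, self.cells_per_colony) < 1:
            raise ValueError("all counts must be >= 1")
        if self.ani_sd <= 0:
            raise ValueError("ani_sd must be > 0")
        means = self.resolved_means()
        if len(means) != self.n_regions:
            raise ValueError("region_ani_means length must equal n_regions")
        lo = min(means) - 3 * self.ani_sd
        hi = max(means) + 3 * self.ani_sd
        if not lo <= self.tau_star <= hi:
            raise ValueError(f"tau_star {self.tau_star} outside region-mean span [{lo}, {hi}]")
        if self.flat_rate is not None and not 0.0 <= self.flat_rate <= 1.0:
            raise ValueError("flat_rate must be in [0, 1]")

    def resolved_means(self) -> tuple[float, ...]:
        if self.region_ani_means is not None:
            return tuple(self.region_ani_means)
        return tuple(np.linspace(20.0, 80.0, self.n_regions))


def gen_explant_assay(cfg: AssaySimConfig) -> tuple[list[RegionAssay], float]:
    """Simulate regional explant assays; returns regions and the planted τ*.

    Per region, the imaged ANI sample is Normal(mean_r, ani_sd) truncated at
    zero; each colony independently draws its own cells from the same
    distribution and its foci count is binomial with the τ*-dependent (or
    flat) rate. Colony outcomes are classed by :func:`score_colonies`, and
    the region's ``pct_gfp`` is the percentage of high-class (>7 foci)
    colonies.
    """
    rng = np.random.default_rng(cfg.seed)
    regions: list[RegionAssay] = []
    for r, mean in enumerate(cfg.resolved_means()):
        a = (0.0 - mean) / cfg.ani_sd
        ani = truncnorm.rvs(a, np.inf, loc=mean, scale=cfg.ani_sd,
                            size=cfg.cells_per_region, random_state=rng)
        foci = np.empty(cfg.colonies_per_region, dtype=int)
        for c in range(cfg.colonies_per_region):
            cells = truncnorm.rvs(a, np.inf, loc=mean, scale=cfg.ani_sd,
                                  size=cfg.cells_per_colony, random_state=rng)
            rate = cfg.flat_rate if cfg.flat_rate is not None else float(np.mean(cells > cfg.tau_star))
            foci[c] = rng.binomial(cfg.cells_per_colony, rate)
        tally = score_colonies(foci, region_id=r)
        regions.append(
            RegionAssay(region_id=r, ani_sample=ani, pct_gfp=tally.pct_gfp_high, tally=tally)
        )
    return regions, cfg.tau_star


DEFAULT_STAGES = ("E6.5", "E6.75", "E7.0", "E7.25", "E7.5")


@dataclass(frozen=True)
class ExprSimConfig:
    """Expression-matrix generator with planted correlated genes.

    Each cell carries a latent AP score ``a ~ U(0,1)`` through a Gaussian
    copula; anchors couple to it with Spearman magnitude ``anchor_rho``
    (*Nanog* increasing, *Sox2* decreasing) and planted genes are calibrated
    so their population Spearman against the matching anchor is
    ``effect_rho`` (and ``-effect_rho`` against the opposing anchor).
    Mouse-level random intercepts of SD ``mouse_effect_sd`` are added per
    (mouse, gene), which distorts pooled correlations but not within-mouse
    ones.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    mice_per_stage: int = 2
    cells_per_mouse: int = 200
    n_null_genes: int = 500
    n_nanog_corr_genes: int = 10
    n_sox2_corr_genes: int = 10
    effect_rho: float = 0.5
    anchor_rho: float = 0.9
    mouse_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("need >= 2 stages (the >=2-timepoints rule must be exercisable)")
        if not 0.0 < self.effect_rho < 1.0:
            raise ValueError("effect_rho must be in (0, 1)")
        if not 0.0 < self.anchor_rho < 1.0:
            raise ValueError("anchor_rho must be in (0, 1)")
        if self.n_null_genes < 1:
            raise ValueError("need >= 1 null gene (false-discovery rate is not estimable otherwise)")
        if min(self.mice_per_stage, self.cells_per_mouse) < 1:
            raise ValueError("counts must be >= 1")
        if self.mouse_effect_sd < 0:
            raise ValueError("mouse_effect_sd must be >= 0")
        if _spearman_to_pearson(self.effect_rho) > _spearman_to_pearson(self.anchor_rho):
            raise ValueError("effect_rho cannot exceed the anchor-latent coupling anchor_rho")


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal conversion: r = 2 sin(pi * rho_s / 6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def gen_expression_matrix(cfg: ExprSimConfig) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Simulate a labelled expression matrix; returns it with the truth gene sets.

    Truth sets: ``nanog_correlated`` genes share the latent link of *Nanog*
    (positive with Nanog, negative with Sox2), ``sox2_correlated`` the
    mirrored link, ``null`` genes are independent of the latent.
    """
    rng = np.random.default_rng(cfg.seed)
    r_anchor = _spearman_to_pearson(cfg.anchor_rho)
    # planted-gene loading on the latent so that gene-vs-anchor Pearson is
    # r_anchor * s = target, i.e. Spearman vs the anchor is effect_rho
    s = _spearman_to_pearson(cfg.effect_rho) / r_anchor

    gene_names = (
        ["Nanog", "Sox2"]
        + [f"NanogCorr{i:03d}" for i in range(cfg.n_nanog_corr_genes)]
        + [f"Sox2Corr{i:03d}" for i in range(cfg.n_sox2_corr_genes)]
        + [f"Null{i:04d}" for i in range(cfg.n_null_genes)]
    )
    loadings = np.concatenate([
        [r_anchor, -r_anchor],
        np.full(cfg.n_nanog_corr_genes, s),
        np.full(cfg.n_sox2_corr_genes, -s),
        np.zeros(cfg.n_null_genes),
    ])
    n_genes = len(gene_names)
    n_cells = len(cfg.stages) * cfg.mice_per_stage * cfg.cells_per_mouse

    latent = rng.standard_normal(n_cells)  # probit of the AP score
    noise = rng.standard_normal((n_cells, n_genes))
    values = latent[:, None] * loadings[None, :] + noise * np.sqrt(1.0 - loadings**2)[None, :]

    stage_labels = np.empty(n_cells, dtype=object)
    mouse_labels = np.empty(n_cells, dtype=object)
    i = 0
    for stage in cfg.stages:
        for m in range(cfg.mice_per_stage):
            sl = slice(i, i + cfg.cells_per_mouse)
            stage_labels[sl] = stage
            mouse_labels[sl] = f"{stage}_m{m + 1}"
            if cfg.mouse_effect_sd > 0:
                values[sl] += rng.normal(0.0, cfg.mouse_effect_sd, size=n_genes)[None, :]
            i += cfg.cells_per_mouse

    expr = ExpressionMatrix(
        values=values,
        gene_names=gene_names,
        cell_stage=stage_labels.astype(str),
        cell_mouse=mouse_labels.astype(str),
    )
    truth = {
        "nanog_correlated": [g for g in gene_names if g.startswith("NanogCorr")],
        "sox2_correlated": [g for g in gene_names if g.startswith("Sox2Corr")],
        "null": [g for g in gene_names if g.startswith("Null")],
    }
    return expr, truth
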