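"""Ground-truthed synthetic data for the imaging and expression arms.

Two generators live here:

* :func:`generate_tumor_image` renders a multi-channel fluorescence scene of
  a tumor whose cells carry a nuclear stain, a nuclear transcription factor
  and one or two cytoplasmic differentiation markers.  A configurable
  fraction of cells is drawn from a low ("lost") marker-intensity mode,
  interspersed at random positions — the variegated, cell-autonomous loss
  pattern seen in de-differentiating tumors.
* :func:`generate_expression_matrix` draws a negative-binomial count matrix
  with block-correlated gene modules, one module down-regulated in the
  second sample group, and a planted transcription-factor regulator inside
  that module.  :func:`generate_celltype_markers` emits matching reference
  expression profiles for four epithelial cell types, engineered so that
  specificity-ranked top-k marker sets overlap pairwise by a configured
  small number of genes.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import LabeledImage

__all__ = [
    "ChannelModel",
    "ImageSimConfig",
    "GroundTruth",
    "ExprSimConfig",
    "ConfigError",
    "PlacementError",
    "generate_tumor_image",
    "sample_cell_levels",
    "generate_expression_matrix",
    "generate_celltype_markers",
    "tf_gene_list",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


class PlacementError(RuntimeError):
    """Nuclei could not be packed into the image at the requested density."""


# ---------------------------------------------------------------------------
# imaging arm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity model for one fluorescence channel.

    Per-cell intensity is ``exp(log_mean + log_sd * z)`` with ``z`` standard
    normal (shared across channels through a Gaussian copula).  Channels with
    ``subject_to_loss`` draw from the *lost* parameters in cells that have
    lost marker expression.
    """

    role: str  # "nuclear_stain" | "nuclear_tf" | "marker"
    log_mean_retained: float
    log_sd_retained: float
    log_mean_lost: float | None = None
    log_sd_lost: float | None = None
    subject_to_loss: bool = False


def default_channel_models() -> dict[str, ChannelModel]:
    return {
        "dna": ChannelModel("nuclear_stain", math.log(2000.0), 0.25),
        "tf": ChannelModel("nuclear_tf", math.log(2200.0), 0.25),
        "marker": ChannelModel(
            "marker",
            math.log(3000.0),
            0.30,
            log_mean_lost=math.log(600.0),
            log_sd_lost=0.40,
            subject_to_loss=True,
        ),
    }


@dataclass
class ImageSimConfig:
    """Scene parameters for one simulated tumor image.

    Intensities are in arbitrary camera units rendered to uint16; lengths in
    pixels.  ``marker_loss_fraction`` is the probability that a cell draws
    its marker intensity from the low mode.
    """

    image_height_px: int = 384
    image_width_px: int = 384
    n_cells: int = 100
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 1.0
    cytoplasm_width_px: float = 10.0
    min_gap_px: float = 2.0
    genotype_label: str = "double_mutant"
    tumor_id: str = "T1"
    marker_loss_fraction: float = 0.5
    channel_models: dict[str, ChannelModel] = field(default_factory=default_channel_models)
    inter_channel_rank_correlation: float = 0.3
    background_level: float = 200.0
    gradient_amplitude: float = 100.0
    read_noise_sd: float = 20.0
    smoothing_sigma: float = 0.8
    rng_seed: int = 0
    max_placement_tries_per_cell: int = 300

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be nonnegative")
        if not 0.0 <= self.marker_loss_fraction <= 1.0:
            raise ConfigError("marker_loss_fraction must lie in [0, 1]")
        if not -1.0 <= self.inter_channel_rank_correlation <= 1.0:
            raise ConfigError("inter_channel_rank_correlation must lie in [-1, 1]")
        for v in (self.background_level, self.gradient_amplitude, self.read_noise_sd):
            if v < 0:
                raise ConfigError("intensity parameters must be nonnegative")
        if self.nucleus_radius_mean <= 0:
            raise ConfigError("nucleus_radius_mean must be positive")
        roles = {m.role for m in self.channel_models.values()}
        if "nuclear_stain" not in roles and "nuclear_tf" not in roles:
            raise ConfigError("need at least one nuclear channel to seed segmentation")
        for name, m in self.channel_models.items():
            if m.subject_to_loss and (m.log_mean_lost is None or m.log_sd_lost is None):
                raise ConfigError(f"channel {name!r} is subject to loss but has no lost-state model")


@dataclass
class GroundTruth:
    """Per-cell truth for a simulated image.

    ``cells`` has one row per cell: centroid, radius, per-channel true mean
    intensity (columns ``true_<channel>``) and per-loss-channel state
    (columns ``state_<channel>``, values "retained"/"lost").  The two label
    rasters encode the nucleus and whole-cell pixel sets (0 = background;
    label k = cell_id k).
    """

    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray


def _place_nuclei(cfg: ImageSimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centers; returns (centers, radii)."""
    radii = np.maximum(2.0, rng.normal(cfg.nucleus_radius_mean, cfg.nucleus_radius_sd, cfg.n_cells))
    centers = np.empty((cfg.n_cells, 2))
    budget = cfg.max_placement_tries_per_cell * max(cfg.n_cells, 1)
    tries = 0
    for i in range(cfg.n_cells):
        margin = radii[i] + cfg.cytoplasm_width_px + 2.0
        while True:
            tries += 1
            if tries > budget:
                raise PlacementError(
                    f"could not place {cfg.n_cells} nuclei in a "
                    f"{cfg.image_height_px}x{cfg.image_width_px} image after {budget} tries"
                )
            r = rng.uniform(margin, cfg.image_height_px - margin)
            c = rng.uniform(margin, cfg.image_width_px - margin)
            if i == 0:
                break
            d = np.hypot(centers[:i, 0] - r, centers[:i, 1] - c)
            if np.all(d > radii[:i] + radii[i] + cfg.min_gap_px):
                break
        centers[i] = (r, c)
    return centers, radii


def _paint_labels(cfg: ImageSimConfig, centers: np.ndarray, radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize nucleus and cell labels.

    A pixel belongs to cell i when ``dist(p, center_i) - r_i`` is minimal
    among all cells and at most ``cytoplasm_width_px``; the nucleus is the
    subset with ``dist <= r_i``.  Ties go to the lower cell id.
    """
    shape = (cfg.image_height_px, cfg.image_width_px)
    nuc = np.zeros(shape, dtype=np.int32)
    cell = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    w = cfg.cytoplasm_width_px
    for i in range(len(radii)):
        r0, c0 = centers[i]
        rad = radii[i]
        reach = rad + w
        rlo, rhi = int(max(0, r0 - reach - 1)), int(min(shape[0], r0 + reach + 2))
        clo, chi = int(max(0, c0 - reach - 1)), int(min(shape[1], c0 + reach + 2))
        rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
        d = np.hypot(rr - r0, cc - c0) - rad
        inside = d <= w
        better = inside & (d < best[rlo:rhi, clo:chi])
        sub_cell = cell[rlo:rhi, clo:chi]
        sub_best = best[rlo:rhi, clo:chi]
        sub_cell[better] = i + 1
        sub_best[better] = d[better]
        nuc_px = d <= 0
        nuc[rlo:rhi, clo:chi][nuc_px] = i + 1
    # nucleus pixels always keep their own label (non-overlap guarantees consistency)
    cell[nuc > 0] = nuc[nuc > 0]
    return nuc, cell


def sample_cell_levels(
    cfg: ImageSimConfig, n_cells: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw per-cell channel intensities and loss states.

    Channels share a Gaussian copula with exchangeable latent correlation
    chosen so that the pairwise Spearman correlation equals
    ``inter_channel_rank_correlation`` (rho_z = 2 sin(pi * rho_s / 6)).
    Returns (levels frame with one column per channel, states dict for
    loss-subject channels).
    """
    names = list(cfg.channel_models)
    k = len(names)
    rho_s = cfg.inter_channel_rank_correlation
    rho_z = 2.0 * math.sin(math.pi * rho_s / 6.0)
    cov = np.full((k, k), rho_z)
    np.fill_diagonal(cov, 1.0)
    # exchangeable correlation must be positive semidefinite
    if k > 1 and rho_z < -1.0 / (k - 1):
        raise ConfigError("inter_channel_rank_correlation too negative for channel count")
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    z = rng.standard_normal((n_cells, k)) @ chol.T
    states: dict[str, np.ndarray] = {}
    levels = {}
    for j, name in enumerate(names):
        m = cfg.channel_models[name]
        if m.subject_to_loss:
            lost = rng.random(n_cells) < cfg.marker_loss_fraction
            states[name] = np.where(lost, "lost", "retained")
            mu = np.where(lost, m.log_mean_lost, m.log_mean_retained)
            sd = np.where(lost, m.log_sd_lost, m.log_sd_retained)
        else:
            mu, sd = m.log_mean_retained, m.log_sd_retained
        levels[name] = np.exp(mu + sd * z[:, j])
    return pd.DataFrame(levels), states


def generate_tumor_image(cfg: ImageSimConfig) -> tuple[LabeledImage, GroundTruth]:
    """Render one simulated tumor image with per-cell ground truth.

    Nuclear channels carry signal only on nucleus pixels; marker channels
    on whole-cell pixels.  A horizontal background ramp and Gaussian read
    noise are added, and the result is clipped to the uint16 range.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    shape = (cfg.image_height_px, cfg.image_width_px)

    if cfg.n_cells > 0:
        centers, radii = _place_nuclei(cfg, rng)
        nuc, cell = _paint_labels(cfg, centers, radii)
        levels, states = sample_cell_levels(cfg, cfg.n_cells, rng)
    else:
        centers = np.empty((0, 2))
        radii = np.empty(0)
        nuc = np.zeros(shape, dtype=np.int32)
        cell = np.zeros(shape, dtype=np.int32)
        levels, states = sample_cell_levels(cfg, 0, rng)

    from scipy.ndimage import gaussian_filter

    ramp = cfg.background_level + cfg.gradient_amplitude * (
        np.arange(shape[1]) / max(shape[1] - 1, 1)
    )
    base = np.broadcast_to(ramp, shape).astype(float)

    channels: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for name, model in cfg.channel_models.items():
        signal = np.zeros(shape)
        mask_raster = nuc if model.role in ("nuclear_stain", "nuclear_tf") else cell
        if cfg.n_cells > 0:
            lut = np.zeros(cfg.n_cells + 1)
            lut[1:] = levels[name].to_numpy()
            signal = lut[mask_raster]
        if cfg.smoothing_sigma > 0:
            signal = gaussian_filter(signal, cfg.smoothing_sigma)
        img = base + signal + rng.normal(0.0, cfg.read_noise_sd, shape)
        channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        roles[name] = model.role

    rows = {
        "cell_id": np.arange(1, cfg.n_cells + 1),
        "row": centers[:, 0],
        "col": centers[:, 1],
        "radius_px": radii,
    }
    for name in cfg.channel_models:
        rows[f"true_{name}"] = levels[name].to_numpy() if cfg.n_cells else np.empty(0)
    for name, st in states.items():
        rows[f"state_{name}"] = st
    truth = GroundTruth(cells=pd.DataFrame(rows), nucleus_labels=nuc, cell_labels=cell)
    image = LabeledImage(channels=channels, roles=roles, tumor_id=cfg.tumor_id, genotype=cfg.genotype_label)
    return image, truth


# ---------------------------------------------------------------------------
# expression arm
# ---------------------------------------------------------------------------

_PAIR_ORDER = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class ExprSimConfig:
    """Parameters of the block-correlated count-matrix generator.

    Genes are laid out deterministically: pair-shared marker genes first,
    then the planted regulator, then type-exclusive marker genes, module
    filler genes, and finally background genes.  Each of ``n_modules``
    modules shares a per-sample latent factor (centered within groups so the
    planted group contrasts are exact).  The ``affected_module_index`` module
    houses both alveolar marker sets and the regulator: its genes shift by
    ``effect_log2fc`` in group B, except the AT1-like markers, which move in
    the opposite direction scaled by ``at1_gain_ratio`` — mirroring the loss
    of type-2 identity alongside a gain of type-1 character.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 8
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (250, 150, 150, 150)
    module_latent_sd: float = 0.28
    gene_noise_sd: float = 0.12
    center_module_latents: bool = True
    library_size: float = 400_000.0
    nb_dispersion: float = 0.01
    affected_module_index: int = 0
    effect_log2fc: float = -1.0
    at1_gain_ratio: float = 0.7
    celltype_names: tuple[str, ...] = ("AT2", "AT1", "club", "ciliated")
    marker_set_size: int = 100
    marker_overlap_counts: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    profile_base: float = 100.0
    profile_high: float = 1000.0
    module_gene_mean: float = 300.0
    background_gene_mean: float = 150.0
    low_expressed_mean: float = 5.0
    low_expressed_fraction: float = 0.3
    n_decoy_tfs: int = 50
    group_labels: tuple[str, str] = ("A", "B")
    depth_range: tuple[float, float] = (0.7, 1.3)
    rng_seed: int = 0

    @property
    def planted_regulator_gene(self) -> str:
        return self._gene_ids()[sum(self.marker_overlap_counts)]

    def _n_shared(self) -> int:
        return int(sum(self.marker_overlap_counts))

    def _exclusive_counts(self) -> list[int]:
        per_type = [0, 0, 0, 0]
        for (a, b), s in zip(_PAIR_ORDER, self.marker_overlap_counts):
            per_type[a] += s
            per_type[b] += s
        return [self.marker_set_size - s for s in per_type]

    def _gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ConfigError("n_genes and n_samples_per_group must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module_sizes sum exceeds n_genes")
        if self.n_modules < 1 or not (0 <= self.affected_module_index < self.n_modules):
            raise ConfigError("affected_module_index out of range")
        if len(self.celltype_names) != 4 or len(self.marker_overlap_counts) != 6:
            raise ConfigError("expected 4 cell types and 6 pairwise overlap counts")
        if self.n_modules < 3:
            raise ConfigError(
                "marker layout needs >= 3 modules (AT1/AT2 share the affected module; "
                "club and ciliated each need a home)"
            )
        if any(c < 0 for c in self.marker_overlap_counts):
            raise ConfigError("overlap counts must be nonnegative")
        if min(self._exclusive_counts()) < 0:
            raise ConfigError("marker_overlap_counts exceed marker_set_size")
        if self.nb_dispersion < 0 or self.module_latent_sd < 0 or self.gene_noise_sd < 0:
            raise ConfigError("variance parameters must be nonnegative")
        needed = self._module_demand()
        for m, (need, size) in enumerate(zip(needed, self.module_sizes)):
            if size < need:
                raise ConfigError(
                    f"module {m} needs >= {need} genes for its marker layout, got {size}"
                )

    def _module_demand(self) -> list[int]:
        """Marker genes that each module must accommodate."""
        demand = [0] * self.n_modules
        homes = self._type_homes()
        for (a, b), s in zip(_PAIR_ORDER, self.marker_overlap_counts):
            demand[homes[a]] += s
        for t, n_excl in enumerate(self._exclusive_counts()):
            demand[homes[t]] += n_excl
        demand[self.affected_module_index] += 1  # regulator
        return demand

    def _type_homes(self) -> list[int]:
        """Home module per cell type.

        The AT2-like and AT1-like markers share the affected module — one
        co-expression cluster carries the bulk of both alveolar identities
        — while the airway types (club, ciliated) get separate homes.
        """
        others = [m for m in range(self.n_modules) if m != self.affected_module_index]
        return [self.affected_module_index, self.affected_module_index, others[0], others[1]]


def _gene_layout(cfg: ExprSimConfig) -> pd.DataFrame:
    """Assign every gene an id, module, marker role and base mean."""
    ids = cfg._gene_ids()
    homes = cfg._type_homes()
    module = np.zeros(cfg.n_genes, dtype=int)  # 0 = background sentinel, re-coded below
    role = np.array(["background"] * cfg.n_genes, dtype=object)
    marker_type = np.array([""] * cfg.n_genes, dtype=object)
    pair_of = np.array([""] * cfg.n_genes, dtype=object)

    idx = 0
    module_fill = [0] * cfg.n_modules  # genes consumed per module so far
    mod_assign = np.full(cfg.n_genes, -1, dtype=int)  # -1 = background
    for (a, b), s in zip(_PAIR_ORDER, cfg.marker_overlap_counts):
        for _ in range(s):
            role[idx] = "shared_marker"
            pair_of[idx] = f"{cfg.celltype_names[a]}|{cfg.celltype_names[b]}"
            mod_assign[idx] = homes[a]
            module_fill[homes[a]] += 1
            idx += 1
    role[idx] = "regulator"
    mod_assign[idx] = cfg.affected_module_index
    module_fill[cfg.affected_module_index] += 1
    idx += 1
    for t, n_excl in enumerate(cfg._exclusive_counts()):
        for _ in range(n_excl):
            role[idx] = "exclusive_marker"
            marker_type[idx] = cfg.celltype_names[t]
            mod_assign[idx] = homes[t]
            module_fill[homes[t]] += 1
            idx += 1
    for m in range(cfg.n_modules):
        while module_fill[m] < cfg.module_sizes[m]:
            role[idx] = "module_filler"
            mod_assign[idx] = m
            module_fill[m] += 1
            idx += 1
    n_background = cfg.n_genes - idx

    base = np.where(mod_assign >= 0, cfg.module_gene_mean, cfg.background_gene_mean).astype(float)
    low = np.zeros(cfg.n_genes, dtype=bool)
    if n_background > 0:
        n_low = int(round(cfg.low_expressed_fraction * n_background))
        low[idx : idx + n_low] = True
        base[idx : idx + n_low] = cfg.low_expressed_mean
    base *= cfg.library_size / base.sum()

    return pd.DataFrame(
        {
            "gene_id": ids,
            "module": mod_assign + 1,  # truth modules are 1-based; 0 = background
            "role": role,
            "marker_type": marker_type,
            "marker_pair": pair_of,
            "base_mean": base,
            "low_expressed": low,
        }
    ).set_index("gene_id")


def generate_expression_matrix(
    cfg: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw the count matrix.

    Returns ``(counts, groups, truth)``: a genes x samples integer frame,
    a per-sample group-label Series, and a per-gene truth table with module
    assignment (1-based; 0 = background), role and ``true_log2fc``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    layout = _gene_layout(cfg)
    n = cfg.n_samples_per_group
    n_samples = 2 * n
    samples = [f"{g}{i + 1}" for g in cfg.group_labels for i in range(n)]
    groups = pd.Series(
        [cfg.group_labels[0]] * n + [cfg.group_labels[1]] * n, index=samples, name="group"
    )

    depth = rng.uniform(*cfg.depth_range, n_samples)
    latent = rng.normal(0.0, cfg.module_latent_sd, (cfg.n_modules, n_samples))
    if cfg.center_module_latents:
        # remove the latent's group-mean so planted group contrasts are exact:
        # the truth table's log2FC holds by construction, not just in expectation
        for g in cfg.group_labels:
            sel = (groups == g).to_numpy()
            latent[:, sel] -= latent[:, sel].mean(axis=1, keepdims=True)
    noise = rng.normal(0.0, cfg.gene_noise_sd, (cfg.n_genes, n_samples))

    log_mu = np.log(layout["base_mean"].to_numpy())[:, None] + noise + np.log(depth)[None, :]
    mod = layout["module"].to_numpy()  # 1-based, 0 background
    in_module = mod > 0
    log_mu[in_module] += latent[mod[in_module] - 1]
    affected = mod == cfg.affected_module_index + 1
    # AT1-like markers inside the affected module move opposite to the rest
    # of the module (alveolar type 1 genes rise while type 2 identity is
    # lost); every other affected gene, including the regulator, carries
    # effect_log2fc.
    at1 = (layout["marker_type"] == cfg.celltype_names[1]).to_numpy()
    per_gene_lfc = np.where(
        affected, np.where(at1, -cfg.at1_gain_ratio * cfg.effect_log2fc, cfg.effect_log2fc), 0.0
    )
    is_b = (groups == cfg.group_labels[1]).to_numpy()
    log_mu[:, is_b] += (per_gene_lfc * math.log(2.0))[:, None]

    mu = np.exp(log_mu)
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=layout.index, columns=samples)

    truth = layout.copy()
    truth["true_log2fc"] = per_gene_lfc
    truth["is_regulator"] = truth["role"] == "regulator"
    return counts_df, groups, truth


def generate_celltype_markers(cfg: ExprSimConfig) -> pd.DataFrame:
    """Reference mean-expression profiles (genes x 4 cell types).

    Exclusive marker genes are high in exactly one type; pair-shared marker
    genes are equally high in their two types (so they tie at zero
    specificity and, by the deterministic gene-id tie-break of the marker
    set builder, fill each type's top-k to exactly k with the configured
    pairwise overlaps); everything else is flat across types.
    """
    cfg.validate()
    layout = _gene_layout(cfg)
    prof = np.full((cfg.n_genes, 4), cfg.profile_base)
    names = list(cfg.celltype_names)
    role = layout["role"].to_numpy()
    for i in range(cfg.n_genes):
        if role[i] == "exclusive_marker":
            prof[i, names.index(layout["marker_type"].iloc[i])] = cfg.profile_high
        elif role[i] == "shared_marker":
            a, b = layout["marker_pair"].iloc[i].split("|")
            prof[i, names.index(a)] = cfg.profile_high
            prof[i, names.index(b)] = cfg.profile_high
    return pd.DataFrame(prof, index=layout.index, columns=names)


def tf_gene_list(cfg: ExprSimConfig) -> list[str]:
    """The planted regulator plus seeded decoy TFs drawn outside the affected module.

    Decoys come from well-expressed genes whose true module differs from the
    affected one, so a correct screen must reject them on the co-expression
    criterion alone.
    """
    cfg.validate()
    layout = _gene_layout(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 7151]))
    eligible = layout.index[
        (layout["module"] != cfg.affected_module_index + 1) & ~layout["low_expressed"]
    ].to_numpy()
    k = min(cfg.n_decoy_tfs, len(eligible))
    decoys = sorted(rng.choice(eligible, size=k, replace=False).tolist())
    return [cfg.planted_regulator_gene] + decoys
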