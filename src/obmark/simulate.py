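"""Synthetic data generators with planted ground truth.

Every downstream stage of the package (gene selection, clustering, marker
screening, laminar histology, particle detection, odor-response statistics)
can be exercised against data whose true structure is known: cell-type
labels, marker genes, soma depths, particle centroids/areas and responsive
cell-odor pairs are all recorded alongside the generated data.

Counts follow a negative-binomial noise model with a Bernoulli expression
gate for planted genes, so both the overdispersion screen and the
fraction-of-expressing-cells marker rules have a well-defined ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

ROLES = ("MC", "TC1", "TC2", "background")


@dataclass(frozen=True)
class MarkerSpec:
    """A planted gene: enriched in one or more cell roles.

    ``log2_fc`` sets the expressing-cell mean relative to the baseline
    negative-binomial mean; ``frac_in``/``frac_out`` are the Bernoulli
    expression-gate probabilities inside and outside the enriched roles.
    """

    gene: str
    roles: tuple[str, ...]
    log2_fc: float = 4.0
    frac_in: float = 0.9
    frac_out: float = 0.02

    def __post_init__(self):
        roles = (self.roles,) if isinstance(self.roles, str) else tuple(self.roles)
        object.__setattr__(self, "roles", roles)
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r}; must be one of {ROLES}")
        if not (0.0 <= self.frac_in <= 1.0 and 0.0 <= self.frac_out <= 1.0):
            raise ValueError("expressing fractions must lie in [0, 1]")
        if not np.isfinite(self.log2_fc):
            raise ValueError("log2 fold change must be finite")


@dataclass
class SimConfig:
    """Configuration for the synthetic count generator."""

    n_cells_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"MC": 150, "TC1": 150, "TC2": 150, "background": 150}
    )
    n_genes: int = 2000
    marker_spec: Sequence[MarkerSpec] = field(default_factory=list)
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.n_cells_per_group or any(n <= 0 for n in self.n_cells_per_group.values()):
            raise ValueError("all group sizes must be positive")
        for r in self.n_cells_per_group:
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r}")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        names = [m.gene for m in self.marker_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in marker_spec")
        if len(names) > self.n_genes:
            raise ValueError("more planted genes than n_genes")


@dataclass
class GroundTruth:
    """Planted truth for a simulated expression matrix."""

    cell_roles: np.ndarray  # role string per cell
    true_markers: tuple[str, ...]  # genes planted as MC-specific


def default_marker_spec() -> list[MarkerSpec]:
    """The default planted-gene panel.

    Three MC-specific marker genes (the screen's targets), the three
    role-identity genes the clustering pipeline keys on (Tbx21 in mitral and
    the Tbx21-positive tufted population, Cck in tufted cells, Slc17a7 in all
    glutamatergic projection neurons), and a small signature block per non-MC
    role so every planted population has a transcriptional identity.
    """
    spec = [
        MarkerSpec("Lbhd2", ("MC",), 4.0, 0.9, 0.02),
        MarkerSpec("Pkib", ("MC",), 4.0, 0.9, 0.02),
        MarkerSpec("Ntng1", ("MC",), 4.0, 0.9, 0.02),
        MarkerSpec("Tbx21", ("MC", "TC1"), 4.0, 0.95, 0.02),
        MarkerSpec("Cck", ("TC1", "TC2"), 4.0, 0.9, 0.03),
        MarkerSpec("Slc17a7", ("MC", "TC1", "TC2"), 4.0, 0.9, 0.03),
    ]
    for role, tag in (("TC1", "Tc1sig"), ("TC2", "Tc2sig"), ("background", "Bgsig")):
        spec.extend(
            MarkerSpec(f"{tag}{i:02d}", (role,), 3.0, 0.9, 0.05) for i in range(8)
        )
    return spec


def default_config(seed: int = 0) -> SimConfig:
    """Default fixture: 600 cells x 2,000 genes, pipeline runs in seconds."""
    return SimConfig(marker_spec=default_marker_spec(), seed=seed)


def generate_counts(config: SimConfig) -> tuple["ExpressionMatrix", GroundTruth]:
    """Draw a genes x cells count matrix with planted structure.

    Baseline genes are NB(nb_mean, nb_dispersion) i.i.d. across cells, with
    per-gene mean scatter (lognormal, sigma=0.5) so the mean-binned Fano
    screen sees a realistic mean-dispersion spread.  Planted genes are
    zero-inflated: a Bernoulli gate at ``frac_in`` (inside enriched roles) or
    ``frac_out`` (outside) times NB at the fold-change-elevated mean.
    """
    from .io import ExpressionMatrix

    config.validate()
    rng = np.random.default_rng(config.seed)

    roles = np.concatenate(
        [np.repeat(r, n) for r, n in config.n_cells_per_group.items()]
    )
    n_cells = roles.size
    n_genes = config.n_genes

    planted = {m.gene: m for m in config.marker_spec}
    gene_names = list(planted)
    gene_names += [f"Gene{i:05d}" for i in range(n_genes - len(gene_names))]

    # per-gene baseline means: lognormal scatter around nb_mean
    base_mean = config.nb_mean * rng.lognormal(0.0, 0.5, size=n_genes)
    size = config.nb_dispersion

    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for g, name in enumerate(gene_names):
        spec = planted.get(name)
        if spec is None:
            m = base_mean[g]
            counts[g] = rng.negative_binomial(size, size / (size + m), size=n_cells)
        else:
            m = config.nb_mean * 2.0**spec.log2_fc
            inside = np.isin(roles, spec.roles)
            gate_p = np.where(inside, spec.frac_in, spec.frac_out)
            gate = rng.random(n_cells) < gate_p
            expr = rng.negative_binomial(size, size / (size + m), size=n_cells)
            counts[g] = np.where(gate, expr, 0)

    true_markers = tuple(m.gene for m in config.marker_spec if set(m.roles) == {"MC"})
    matrix = ExpressionMatrix(
        counts=counts,
        gene_names=np.asarray(gene_names, dtype=object),
        cell_ids=np.asarray([f"cell{i:05d}" for i in range(n_cells)], dtype=object),
    )
    return matrix, GroundTruth(cell_roles=roles, true_markers=true_markers)


# ---------------------------------------------------------------------------
# laminar histology scenes


def generate_laminar_scene(
    n_mc: int = 100,
    n_tc: int = 100,
    mc_depth_dist=None,
    tc_depth_dist=None,
    epl_thickness_px: float = 100.0,
    width_px: float = 800.0,
    scale_um_per_px: float = 1.2,
    seed: int = 0,
):
    """Build a laminar scene with straight parallel layer boundaries.

    The mitral cell layer (MCL) boundary sits at depth 0 and the lower
    glomerular-layer (GL) boundary at depth 1, ``epl_thickness_px`` pixels
    away.  Soma depths are drawn from the supplied frozen distributions
    (defaults: MCs hug the MCL, TCs spread through the upper EPL) and placed
    at uniform lateral positions.  Returns ``(scene, depths)`` where
    ``depths`` maps soma index to its planted normalized depth (MCs first).
    """
    from .histology import LaminarScene

    if n_mc < 0 or n_tc < 0 or epl_thickness_px <= 0:
        raise ValueError("counts must be non-negative and thickness positive")
    rng = np.random.default_rng(seed)
    if mc_depth_dist is None:
        a, b = (0.0 - 0.12) / 0.08, (1.0 - 0.12) / 0.08
        mc_depth_dist = stats.truncnorm(a, b, loc=0.12, scale=0.08)
    if tc_depth_dist is None:
        tc_depth_dist = stats.uniform(0.35, 0.6)

    y_mcl = 100.0
    xs = np.linspace(0.0, width_px, 9)
    mcl = np.column_stack([xs, np.full_like(xs, y_mcl)])
    gl = np.column_stack([xs, np.full_like(xs, y_mcl + epl_thickness_px)])

    depths = np.concatenate(
        [
            mc_depth_dist.rvs(size=n_mc, random_state=rng) if n_mc else np.empty(0),
            tc_depth_dist.rvs(size=n_tc, random_state=rng) if n_tc else np.empty(0),
        ]
    )
    if depths.size and (depths.min() < -1 or depths.max() > 2):
        raise ValueError("depth distribution not supported on the normalized axis")
    # keep somata away from the lateral edges so projections stay interior
    x_soma = rng.uniform(0.05 * width_px, 0.95 * width_px, size=depths.size)
    somata = np.column_stack([x_soma, y_mcl + depths * epl_thickness_px])

    scene = LaminarScene(
        mcl_boundary=mcl,
        gl_boundary=gl,
        somata=somata,
        scale_um_per_px=scale_um_per_px,
    )
    return scene, depths


# ---------------------------------------------------------------------------
# particle masks


def generate_particle_mask(
    blobs: Sequence[tuple[tuple[float, float], float]],
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
):
    """Rasterize non-overlapping discs into a binary mask.

    ``blobs`` is a list of ((row, col), radius_px).  Pixels whose center lies
    within ``radius`` of the disc center (inclusive) are set, matching the
    inclusive-boundary convention of common raster tools.  Returns
    ``(mask, truth)`` where ``truth`` is a list of dicts holding each disc's
    planted center and its *rasterized* pixel area.
    """
    mask = np.zeros(image_shape, dtype=bool)
    for i, ((r1, c1), rad1) in enumerate(blobs):
        if not (rad1 <= r1 <= image_shape[0] - rad1 and rad1 <= c1 <= image_shape[1] - rad1):
            raise ValueError(f"blob {i} extends outside the image")
        for (r2, c2), rad2 in blobs[i + 1 :]:
            if np.hypot(r1 - r2, c1 - c2) <= rad1 + rad2 + 1:
                raise ValueError("blobs overlap")

    rows, cols = np.indices(image_shape)
    truth = []
    for (r0, c0), radius in blobs:
        inside = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
        mask |= inside
        truth.append({"centroid": (r0, c0), "area_px": int(inside.sum())})
    return mask, truth


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass
class TraceSet:
    """Fluorescence traces for cells x odors x trials."""

    f: np.ndarray  # (n_cells, n_odors, n_trials, n_frames), raw fluorescence
    frame_rate: float  # Hz
    onset_frame: int  # inhalation onset, frames from trial start
    baseline_f: float = 100.0

    @property
    def n_frames(self) -> int:
        return self.f.shape[-1]


def generate_traces(
    n_cells: int = 45,
    n_odors: int = 6,
    responsive_pairs: set[tuple[int, int]] | None = None,
    effect_z: float = 4.0,
    frame_rate: float = 30.0,
    noise_sd: float = 0.05,
    n_trials: int = 4,
    trial_len_s: float = 6.0,
    onset_s: float = 3.0,
    baseline_f: float = 100.0,
    seed: int = 0,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate calcium traces with planted responsive cell-odor pairs.

    ``noise_sd`` is the baseline frame-to-frame dF/F noise SD of the
    *trial-averaged* trace: per-trial frame noise is scaled by sqrt(n_trials),
    and each trial's odor window additionally carries a gain noise of the same
    magnitude (trial-to-trial response variability).  A responsive pair gets a
    mean dF/F shift of ``effect_z * noise_sd`` in the 1 s window from
    inhalation onset, so the trial-averaged odor-window Z score is ~N(effect_z, 1)
    and ~N(0, 1) for unplanted pairs.
    """
    if effect_z < 0:
        raise ValueError("effect_z must be non-negative")
    responsive_pairs = set(responsive_pairs or ())
    for c, o in responsive_pairs:
        if not (0 <= c < n_cells and 0 <= o < n_odors):
            raise ValueError(f"responsive pair {(c, o)} out of range")

    rng = np.random.default_rng(seed)
    n_frames = int(round(trial_len_s * frame_rate))
    onset = int(round(onset_s * frame_rate))
    win = int(round(1.0 * frame_rate))
    if onset + win > n_frames:
        raise ValueError("odor window extends past the trial")

    shape = (n_cells, n_odors, n_trials, n_frames)
    dff = rng.normal(0.0, noise_sd * np.sqrt(n_trials), size=shape)
    # per-trial odor-window gain noise, plus the planted mean shift
    gain = rng.normal(0.0, noise_sd * np.sqrt(n_trials), size=shape[:3])
    shift = np.zeros((n_cells, n_odors))
    for c, o in responsive_pairs:
        shift[c, o] = effect_z * noise_sd
    dff[..., onset : onset + win] += (gain + shift[..., None])[..., None]

    f = baseline_f * (1.0 + dff)
    traces = TraceSet(f=f, frame_rate=frame_rate, onset_frame=onset, baseline_f=baseline_f)
    truth = GroundTruth(cell_roles=np.repeat("MC", n_cells), true_markers=())
    truth.responsive_pairs = frozenset(responsive_pairs)  # type: ignore[attr-defined]
    return traces, truth
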