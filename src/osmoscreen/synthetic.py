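"""Synthetic data generators with known ground truth.

Every downstream stage of the toolkit (screen hit calling, plate Z-scores,
label-swap phosphopeptide filtering, image metrics) can be exercised on data
produced here, so the whole pipeline is testable without any external
download.  All generators are driven by a single integer seed per call and
use a private :class:`numpy.random.Generator`; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticScreenConfig",
    "GroundTruth",
    "LabelSwapConfig",
    "FilamentSceneConfig",
    "simulate_screen",
    "simulate_label_swap",
    "render_filament_image",
    "simulate_roi_movie",
    "simulate_plate",
]


# ---------------------------------------------------------------------------
# pooled barcoded screen under competitive growth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScreenConfig:
    """Parameters of a simulated pooled insertional-mutant screen.

    The pool grows for ``doublings`` generations; a mutant allele of a hit
    gene carries a per-doubling fitness deficit ``selection_coefficient`` s,
    so its abundance after growth under treatment is proportional to
    ``2**(doublings * (1 - s))`` while every allele grows as ``2**doublings``
    under the control condition.  Reads are drawn multinomially at
    ``read_depth`` per sample (optionally Dirichlet-multinomial when
    ``overdispersion`` is set).
    """

    n_genes: int = 1000
    alleles_per_gene: int | Sequence[int] = 5
    n_hit_genes: int = 20
    selection_coefficient: float = 0.5
    doublings: float = 4.0
    read_depth: int = 10_000_000
    replicates: int = 1
    seed: int = 0
    #: Dirichlet-multinomial concentration; ``None`` disables overdispersion
    #: (pure multinomial reads, the default model).
    overdispersion: float | None = None

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_hit_genes > self.n_genes or self.n_hit_genes < 0:
            raise ValueError("need 0 <= n_hit_genes <= n_genes")
        if not 0.0 <= self.selection_coefficient <= 1.0:
            raise ValueError("selection_coefficient must lie in [0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")

    def allele_counts(self) -> np.ndarray:
        if np.isscalar(self.alleles_per_gene):
            return np.full(self.n_genes, int(self.alleles_per_gene))
        arr = np.asarray(self.alleles_per_gene, dtype=int)
        if arr.shape != (self.n_genes,):
            raise ValueError("alleles_per_gene list must have one entry per gene")
        return arr


@dataclass
class GroundTruth:
    """True selection coefficients and model-expected phenotype ratios.

    ``expected_phi`` is the per-allele growth expectation ``2**(-g*s)``.
    Neutral alleles (s = 0) have expected Φ = 1.  Because the observed Φ is a
    ratio of within-sample relative abundances, realized values additionally
    carry a common pool-composition factor ``N / Σ_j 2**(-g*s_j)`` shared by
    every allele; it equals 1 for an all-neutral pool and is ≈1 whenever hits
    are sparse.
    """

    gene_s: pd.Series
    allele_expected_phi: pd.Series
    doublings: float

    @property
    def hit_genes(self) -> list[str]:
        return list(self.gene_s.index[self.gene_s > 0])

    @property
    def composition_factor(self) -> float:
        """N / Σ_j 2**(-g*s_j); multiplies every allele's realized Φ."""
        phi = self.allele_expected_phi.to_numpy()
        return len(phi) / phi.sum()


def simulate_screen(
    config: SyntheticScreenConfig,
    *,
    sampling: str = "multinomial",
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a pooled barcoded screen under competitive growth.

    Parameters
    ----------
    config
        Screen parameters; see :class:`SyntheticScreenConfig`.
    sampling
        ``"multinomial"`` draws integer reads at ``read_depth`` per sample;
        ``"none"`` returns exact expected read counts (float) for
        deterministic closed-form checks.

    Returns
    -------
    counts : DataFrame
        Barcodes × samples.  Samples are named ``control_r<k>`` /
        ``treatment_r<k>`` for each replicate k.
    annotation : DataFrame
        ``barcode → gene_id, allele_index``.
    truth : GroundTruth
    """
    config.validate()
    if sampling not in ("multinomial", "none"):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    rng = np.random.default_rng(config.seed)

    alleles = config.allele_counts()
    gene_ids = np.repeat([f"gene{i:05d}" for i in range(config.n_genes)], alleles)
    allele_idx = np.concatenate([np.arange(k) for k in alleles])
    barcodes = np.array([f"bc{i:06d}" for i in range(len(gene_ids))])

    hit_gene_pos = rng.choice(config.n_genes, size=config.n_hit_genes, replace=False)
    s_per_gene = np.zeros(config.n_genes)
    s_per_gene[hit_gene_pos] = config.selection_coefficient
    s_per_allele = np.repeat(s_per_gene, alleles)

    g = config.doublings
    # equal inoculum; control grows 2^g for everyone, treatment 2^{g(1-s)}
    p_control = np.full(len(barcodes), 1.0 / len(barcodes))
    w_treat = np.power(2.0, -g * s_per_allele)  # 2^{g(1-s)} / 2^{g}
    p_treat = w_treat / w_treat.sum()

    def draw(p: np.ndarray) -> np.ndarray:
        if sampling == "none":
            return p * config.read_depth
        if config.overdispersion is not None:
            p = rng.dirichlet(p * config.overdispersion)
        return rng.multinomial(config.read_depth, p)

    cols: dict[str, np.ndarray] = {}
    for r in range(1, config.replicates + 1):
        cols[f"control_r{r}"] = draw(p_control)
        cols[f"treatment_r{r}"] = draw(p_treat)

    counts = pd.DataFrame(cols, index=pd.Index(barcodes, name="barcode"))
    annotation = pd.DataFrame(
        {"gene_id": gene_ids, "allele_index": allele_idx},
        index=counts.index,
    )
    truth = GroundTruth(
        gene_s=pd.Series(s_per_gene, index=[f"gene{i:05d}" for i in range(config.n_genes)]),
        allele_expected_phi=pd.Series(np.power(2.0, -g * s_per_allele), index=counts.index),
        doublings=g,
    )
    return counts, annotation, truth


# ---------------------------------------------------------------------------
# reciprocal 14N/15N label-swap phosphoproteomics ratio tables
# ---------------------------------------------------------------------------

@dataclass
class LabelSwapConfig:
    """Planted-truth generator for metabolic label-swap ratio tables.

    Each replicate is an experimental pair of one treated and one control
    culture; in a *forward* pair the treated cells carry the light (14N)
    label so the raw light/heavy ratio equals treated/control, while in a
    *reverse* pair the labels are exchanged and the raw ratio equals
    control/treated.  ``n_changed`` peptides have a true treated/control
    fold change of ``true_fold``; the rest are unchanged.  Noise is additive
    on the log2-ratio scale.
    """

    n_peptides: int = 100
    n_changed: int = 10
    true_fold: float = 4.0
    replicates: int = 3
    #: orientation of each replicate pair; length must equal ``replicates``.
    orientation_pattern: Sequence[str] = ("forward", "reverse", "forward")
    noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_changed > self.n_peptides or self.n_changed < 0:
            raise ValueError("need 0 <= n_changed <= n_peptides")
        if self.true_fold <= 0:
            raise ValueError("true_fold must be positive")
        if len(self.orientation_pattern) != self.replicates:
            raise ValueError("orientation_pattern length must equal replicates")
        if any(o not in ("forward", "reverse") for o in self.orientation_pattern):
            raise ValueError("orientations must be 'forward' or 'reverse'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_label_swap(config: LabelSwapConfig) -> pd.DataFrame:
    """Generate one measurement row per (peptide, replicate).

    Returns a DataFrame with columns ``peptide_id, protein_id, site,
    replicate, orientation, raw_ratio, true_fold`` (the last column is the
    planted treated/control truth for convenience in tests).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    changed = np.zeros(config.n_peptides, dtype=bool)
    changed[rng.choice(config.n_peptides, size=config.n_changed, replace=False)] = True
    log2_true = np.where(changed, np.log2(config.true_fold), 0.0)

    rows = []
    for r, orient in enumerate(config.orientation_pattern, start=1):
        noise = rng.normal(0.0, config.noise_sd, size=config.n_peptides)
        log2_tc = log2_true + noise  # treated/control on log2 scale
        raw = np.exp2(log2_tc if orient == "forward" else -log2_tc)
        for i in range(config.n_peptides):
            rows.append(
                {
                    "peptide_id": f"pep{i:05d}",
                    "protein_id": f"prot{i // 2:05d}",
                    "site": f"S{10 + i}",
                    "replicate": r,
                    "orientation": orient,
                    "raw_ratio": raw[i],
                    "true_fold": 2.0 ** log2_true[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic actin filament scenes
# ---------------------------------------------------------------------------

@dataclass
class FilamentSceneConfig:
    """Scene description for rendered actin-like filament crops.

    ``bundling`` ≥ 1 concentrates the constant total fluorescence signal
    onto fewer, proportionally brighter cables — the image phenotype that
    the intensity-skewness bundling index is designed to detect.
    """

    size: int = 128
    pixel_size_um: float = 0.1
    n_filaments: int = 12
    orientation: float = 0.0
    bundling: float = 1.0
    noise_sd: float = 2.0
    background: float = 10.0
    total_signal: float = 40000.0
    seed: int = 0

    def validate(self) -> None:
        if not -90.0 <= self.orientation <= 90.0:
            raise ValueError("orientation must lie in [-90, 90] degrees")
        if self.bundling < 1.0:
            raise ValueError("bundling must be >= 1")
        if self.size < 8:
            raise ValueError("image too small")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")


def _draw_horizontal_lines(size: int, rows: np.ndarray, amplitude: float) -> np.ndarray:
    img = np.zeros((size, size), dtype=float)
    for r in rows:
        img[int(r) % size, :] += amplitude
    return img


def render_filament_image(config: FilamentSceneConfig) -> np.ndarray:
    """Render a grayscale crop of line-like structures plus Gaussian noise.

    The scene is generated in a canonical horizontal orientation (filament
    rows chosen at random, seeded) and then rotated to ``orientation``
    degrees counter-clockwise; multiples of 90° use an exact array rotation.
    Total filament signal is held constant across bundling levels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_eff = max(1, int(round(config.n_filaments / config.bundling))) if config.n_filaments else 0
    img = np.full((config.size, config.size), config.background, dtype=float)
    if n_eff:
        rows = rng.choice(config.size, size=n_eff, replace=False)
        amp = config.total_signal / (n_eff * config.size)
        img += _draw_horizontal_lines(config.size, rows, amp)
    img += rng.normal(0.0, config.noise_sd, size=img.shape)

    theta = float(config.orientation)
    if theta % 90 == 0:
        img = np.rot90(img, k=int(theta // 90) % 4)
    elif theta != 0.0:
        from skimage.transform import rotate

        img = rotate(img, theta, order=3, mode="reflect", preserve_range=True)
    return img


# ---------------------------------------------------------------------------
# calcium-spike ROI movies
# ---------------------------------------------------------------------------

def simulate_roi_movie(
    n_frames: int,
    frame_shape: tuple[int, int],
    spike_schedule: Sequence[tuple[int, int, int]],
    spike_area_px: int = 12,
    amplitude: float = 150.0,
    noise_sd: float = 2.0,
    background: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build an 8-bit movie with planted suprathreshold calcium-like events.

    Parameters
    ----------
    spike_schedule
        Iterable of ``(frame, row, col)`` event centers.  Each event paints a
        compact blob of ``spike_area_px`` pixels at that frame.
    Returns
    -------
    stack : uint8 array, shape (n_frames, H, W)
    truth : DataFrame with columns frame, row, col, n_px
    """
    if spike_area_px < 1:
        raise ValueError("spike area must be >= 1 pixel")
    h, w = frame_shape
    for f, r, c in spike_schedule:
        if not (0 <= f < n_frames and 0 <= r < h and 0 <= c < w):
            raise ValueError(f"scheduled spike ({f},{r},{c}) outside the movie")

    rng = np.random.default_rng(seed)
    stack = rng.normal(background, noise_sd, size=(n_frames, h, w))

    # nearest-to-center pixel offsets forming a compact blob of exactly n px
    radius = int(np.ceil(np.sqrt(spike_area_px))) + 1
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    order = np.argsort((yy**2 + xx**2).ravel(), kind="stable")
    offsets = np.column_stack([yy.ravel()[order], xx.ravel()[order]])[:spike_area_px]

    truth_rows = []
    for f, r, c in spike_schedule:
        n_painted = 0
        for dy, dx in offsets:
            y, x = r + dy, c + dx
            if 0 <= y < h and 0 <= x < w:
                stack[f, y, x] += amplitude
                n_painted += 1
        truth_rows.append({"frame": f, "row": r, "col": c, "n_px": n_painted})

    stack = np.clip(stack, 0, 255).astype(np.uint8)
    truth = pd.DataFrame(truth_rows, columns=["frame", "row", "col", "n_px"])
    return stack, truth


# ---------------------------------------------------------------------------
# secondary-screen plates
# ---------------------------------------------------------------------------

def simulate_plate(
    layout: pd.DataFrame,
    growth: dict[str, float],
    well_noise_sd: float = 0.0,
    seed: int = 0,
    render_image: bool = False,
    well_radius_px: int = 10,
    well_pitch_px: int = 30,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-well growth intensities for a secondary-screen plate.

    ``layout`` needs columns ``row, col, genotype, is_wt`` (and optionally
    ``excluded``).  ``growth`` maps genotype → mean 8-bit intensity.  With
    ``render_image=True`` an 8-bit RGB plate scan is also returned, each well
    drawn as a uniform disk of its intensity on a black background.
    """
    if "excluded" not in layout.columns:
        layout = layout.assign(excluded=False)
    if int(layout["is_wt"].sum()) < 2:
        raise ValueError("plate layout must contain at least 2 wild-type wells")

    rng = np.random.default_rng(seed)
    vals = []
    for _, wl in layout.iterrows():
        mu = growth[wl["genotype"]]
        vals.append(mu + (rng.normal(0.0, well_noise_sd) if well_noise_sd > 0 else 0.0))
    grid = layout.copy()
    grid["intensity"] = np.clip(vals, 0, 255)

    if not render_image:
        return grid

    n_rows = int(grid["row"].max()) + 1
    n_cols = int(grid["col"].max()) + 1
    img = np.zeros((n_rows * well_pitch_px, n_cols * well_pitch_px, 3), dtype=np.uint8)
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    for _, wl in grid.iterrows():
        cy = int(wl["row"]) * well_pitch_px + well_pitch_px // 2
        cx = int(wl["col"]) * well_pitch_px + well_pitch_px // 2
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= well_radius_px**2
        img[mask] = int(round(wl["intensity"]))
    return grid, img
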