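"""Ground-truthed synthetic inputs for every stage of the pipeline.

Three generators emulate the statistical structure the analysis assumes:

* an expression matrix (TPM) with three planted malignant states defined by
  disjoint gene signatures, a latent factor inducing known Pearson
  correlations between chosen genes and a designated target gene, and
  dropout noise;
* a two-channel punctum field with a planted colocalized fraction at
  sub-radius offsets;
* single-ROI fluorescence time series with planted baseline, transient
  amplitude and duration.

All planted quantities (labels, coordinates, amplitudes) are returned
alongside the data; the same seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import STATE_NAMES, ExpressionMatrix, Signature
from .traces import FluorTrace

__all__ = [
    "SyntheticExpressionSpec",
    "SyntheticImageSpec",
    "SyntheticTraceSpec",
    "ExpressionTruth",
    "ImageTruth",
    "TraceTruth",
    "generate_expression",
    "generate_puncta_image",
    "generate_trace",
]


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of the planted-state expression simulation.

    Expression is generated in log2 units (Gaussian around per-gene means),
    shifted by ``signature_effect`` for a state's signature genes in cells of
    that state, then inverted to TPM via ``tpm = 10 * (2**x - 1)`` so that the
    pipeline's log transform recovers the latent values exactly (up to the
    clip of negative log values at zero).
    """

    n_cells: int = 300
    n_genes: int = 1000
    state_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    signature_size: int = 30
    signature_effect: float = 2.0
    target_gene: str = "NTRK2"
    target_gene_correlations: Mapping[str, float] = field(default_factory=dict)
    dropout_rate: float = 0.1
    noise_sd: float = 0.5
    base_mean_range: tuple = (0.5, 3.5)
    corr_mean_range: tuple = (1.5, 3.0)
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.state_proportions) != 3:
            raise ValueError("state_proportions must have three entries")
        if abs(sum(self.state_proportions) - 1.0) > 1e-9:
            raise ValueError("state_proportions must sum to 1")
        if any(p < 0 for p in self.state_proportions):
            raise ValueError("state_proportions must be non-negative")
        for g, rho in self.target_gene_correlations.items():
            if abs(rho) > 1.0:
                raise ValueError(f"|rho| must be <= 1 (gene {g!r}: {rho})")
        if self.target_gene in self.target_gene_correlations:
            raise ValueError("target gene cannot appear in target_gene_correlations")
        needed = 1 + len(self.target_gene_correlations) + 3 * self.signature_size
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for target + correlated "
                f"+ signature genes ({needed})"
            )
        if self.dropout_rate < 0 or self.dropout_rate >= 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class ExpressionTruth:
    """Planted ground truth accompanying a synthetic expression matrix."""

    states: pd.Series  # per-cell planted state label
    correlations: dict  # gene -> planted latent Pearson rho with the target
    signatures: dict  # state name -> Signature
    latent_log: np.ndarray  # pre-clip, pre-dropout log2 matrix


def _state_labels(n_cells: int, proportions: Sequence[float], rng) -> np.ndarray:
    counts = [int(math.floor(p * n_cells)) for p in proportions]
    # distribute the rounding remainder to the largest fractional parts
    rem = n_cells - sum(counts)
    fracs = np.argsort([-(p * n_cells - math.floor(p * n_cells)) for p in proportions])
    for i in range(rem):
        counts[fracs[i % 3]] += 1
    labels = np.repeat(list(STATE_NAMES), counts)
    rng.shuffle(labels)
    return labels


def generate_expression(spec: SyntheticExpressionSpec):
    """Simulate a TPM matrix with planted states and target-gene correlations.

    Returns ``(matrix, truth)`` where ``matrix`` is a TPM-scale
    :class:`~gliosynapse.expression.ExpressionMatrix` and ``truth`` an
    :class:`ExpressionTruth`.  The planted correlation is exact for the
    latent (pre-clip, pre-dropout) log-space matrix by the latent-factor
    construction: the target gene's deviation is the factor itself and each
    correlated gene loads ``rho`` on it plus ``sqrt(1 - rho**2)``
    idiosyncratic noise.
    """
    rng = np.random.default_rng(spec.seed)
    corr_genes = list(spec.target_gene_correlations)
    n_sig = 3 * spec.signature_size

    gene_ids = [spec.target_gene]
    gene_ids += corr_genes
    sig_names = {}
    for state in STATE_NAMES:
        tag = state.split("-")[0]
        names = [f"SIG_{tag}_{i:03d}" for i in range(spec.signature_size)]
        sig_names[state] = names
        gene_ids += names
    n_bg = spec.n_genes - len(gene_ids)
    gene_ids += [f"G{i:05d}" for i in range(n_bg)]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene names collide (check target_gene_correlations keys)")
    gene_index = pd.Index(gene_ids)

    cell_ids = pd.Index([f"cell{i:04d}" for i in range(spec.n_cells)])
    states = _state_labels(spec.n_cells, spec.state_proportions, rng)

    means = rng.uniform(*spec.base_mean_range, size=spec.n_genes)
    # keep the target and correlated genes well expressed so they stay
    # analysable and rarely clip at zero
    n_corr_block = 1 + len(corr_genes)
    means[:n_corr_block] = rng.uniform(*spec.corr_mean_range, size=n_corr_block)

    x = means[:, None] + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_cells)
    )
    # latent-factor correlation structure
    z = rng.standard_normal(spec.n_cells)
    x[0] = means[0] + spec.noise_sd * z
    for j, g in enumerate(corr_genes, start=1):
        rho = spec.target_gene_correlations[g]
        eps = rng.standard_normal(spec.n_cells)
        x[j] = means[j] + spec.noise_sd * (rho * z + math.sqrt(1 - rho**2) * eps)

    # planted state programmes
    signatures = {}
    for s, state in enumerate(STATE_NAMES):
        idx = gene_index.get_indexer(sig_names[state])
        in_state = states == state
        x[np.ix_(idx, in_state)] += spec.signature_effect
        signatures[state] = Signature(name=state, genes=tuple(sig_names[state]))

    latent = x.copy()
    x = np.clip(x, 0.0, None)
    tpm = 10.0 * (np.exp2(x) - 1.0)
    if spec.dropout_rate > 0:
        keep = rng.random(tpm.shape) >= spec.dropout_rate
        tpm = tpm * keep

    sample = np.array(
        [f"sample{i % spec.n_samples}" for i in range(spec.n_cells)], object
    )
    meta = pd.DataFrame(
        {"sample": sample, "malignant": True}, index=cell_ids
    )
    matrix = ExpressionMatrix(
        values=tpm, gene_ids=gene_index, cell_ids=cell_ids, cell_meta=meta
    )
    truth = ExpressionTruth(
        states=pd.Series(states, index=cell_ids, name="true_state"),
        correlations=dict(spec.target_gene_correlations),
        signatures=signatures,
        latent_log=latent,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# puncta images


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of the two-channel punctum field simulation.

    A fraction ``coloc_fraction`` of postsynaptic puncta is placed within
    ``offset_max_um`` of a (distinct) presynaptic punctum; the remainder are
    kept at least ``noncoloc_margin_um`` from every presynaptic punctum so
    the planted colocalized fraction is unambiguous at the analysis radius.
    Spots are isotropic Gaussians with peak amplitudes drawn uniformly in
    ``[0.5, 1] * peak_intensity``.
    """

    field_size_um: float = 64.0
    pixel_size_um: float = 0.1
    n_pre: int = 200
    n_post: int = 200
    coloc_fraction: float = 0.5
    offset_max_um: float = 0.5
    psf_sigma_um: float = 0.2
    peak_intensity: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 5.0
    min_separation_um: float = 1.2
    noncoloc_margin_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.pixel_size_um <= 0 or self.field_size_um <= 0:
            raise ValueError("field and pixel sizes must be positive")
        if self.offset_max_um < 0:
            raise ValueError("offset_max_um must be >= 0")


@dataclass
class ImageTruth:
    """Planted punctum coordinates (µm, (x, y)) and colocalization flags."""

    pre_coords_um: np.ndarray
    post_coords_um: np.ndarray
    coloc_flags: np.ndarray  # bool per post punctum


def _place_points(rng, n, lo, hi, min_sep, avoid=None, avoid_dist=0.0, max_tries=20000):
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place puncta with the requested separations; "
                "lower the counts or separations"
            )
        p = rng.uniform(lo, hi, size=2)
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            continue
        if (
            avoid is not None
            and len(avoid)
            and np.min(np.linalg.norm(avoid - p, axis=1)) < avoid_dist
        ):
            continue
        pts.append(p)
    return np.array(pts).reshape(n, 2)


def _render_spots(shape, coords_px, amps, sigma_px):
    img = np.zeros(shape)
    half = max(1, int(math.ceil(4 * sigma_px)))
    for (cx, cy), a in zip(coords_px, amps):
        x0, x1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
        y0, y1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, shape[1])
        y0, y1 = max(y0, 0), min(y1, shape[0])
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)[:, None]
        img[y0:y1, x0:x1] += a * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma_px**2)
        )
    return img


def generate_puncta_image(spec: SyntheticImageSpec):
    """Simulate a two-channel punctum field with a planted colocalized fraction.

    Returns ``(field, truth)`` where ``field`` is a
    :class:`~gliosynapse.imaging.PunctaField` (channel 0 presynaptic,
    channel 1 postsynaptic) and ``truth`` an :class:`ImageTruth`.
    """
    from .imaging import PunctaField  # deferred to avoid an import cycle

    if spec.psf_sigma_um < spec.pixel_size_um / 2:
        warnings.warn(
            "psf_sigma_um < pixel_size_um/2: spots are undersampled",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    size_px = int(spec.field_size_um / spec.pixel_size_um)
    margin = 4 * spec.psf_sigma_um + spec.offset_max_um + spec.pixel_size_um
    lo, hi = margin, spec.field_size_um - margin

    # extra presynaptic spacing guarantees colocalized partners cannot merge
    pre_sep = spec.min_separation_um + 2 * spec.offset_max_um
    pre = _place_points(rng, spec.n_pre, lo, hi, pre_sep)

    n_coloc = int(round(spec.coloc_fraction * spec.n_post))
    if n_coloc > spec.n_pre:
        raise ValueError("coloc_fraction * n_post exceeds n_pre")
    partners = rng.choice(spec.n_pre, size=n_coloc, replace=False) if n_coloc else []
    post = []
    for i in partners:
        for _ in range(100):
            theta = rng.uniform(0, 2 * math.pi)
            r = rng.uniform(0, spec.offset_max_um)
            p = pre[i] + r * np.array([math.cos(theta), math.sin(theta)])
            if not post or np.min(
                np.linalg.norm(np.array(post) - p, axis=1)
            ) >= spec.min_separation_um:
                break
        post.append(p)
    n_free = spec.n_post - n_coloc
    if n_free:
        free = _place_points(
            rng,
            n_free,
            lo,
            hi,
            spec.min_separation_um,
            avoid=pre,
            avoid_dist=spec.noncoloc_margin_um,
        )
        # keep non-colocalized posts clear of already-placed posts too
        post_arr = np.array(post).reshape(-1, 2)
        kept = []
        for p in free:
            if len(post_arr) and np.min(
                np.linalg.norm(post_arr - p, axis=1)
            ) < spec.min_separation_um:
                p = _place_points(
                    rng,
                    1,
                    lo,
                    hi,
                    spec.min_separation_um,
                    avoid=np.vstack([pre * 1.0, post_arr])
                    if len(post_arr)
                    else pre,
                    avoid_dist=spec.noncoloc_margin_um,
                )[0]
            kept.append(p)
            post_arr = np.vstack([post_arr, p]) if len(post_arr) else p[None]
        post.extend(kept)
    post = np.array(post).reshape(spec.n_post, 2)
    flags = np.zeros(spec.n_post, dtype=bool)
    flags[: len(partners)] = True

    sigma_px = spec.psf_sigma_um / spec.pixel_size_um
    shape = (size_px, size_px)
    channels = []
    for coords in (pre, post):
        amps = spec.peak_intensity * rng.uniform(0.5, 1.0, size=len(coords))
        img = _render_spots(shape, coords / spec.pixel_size_um, amps, sigma_px)
        img += spec.background_level
        if spec.noise_sd > 0:
            img += spec.noise_sd * rng.standard_normal(shape)
        channels.append(np.clip(img, 0.0, None))
    field = PunctaField(
        image=np.stack(channels),
        pixel_size_um=spec.pixel_size_um,
        channel_roles={"pre": 0, "post": 1},
    )
    return field, ImageTruth(pre_coords_um=pre, post_coords_um=post, coloc_flags=flags)


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Parameters of the single-ROI fluorescence trace simulation.

    ``trace = background_f + baseline_f + transient + noise`` with a boxcar
    (default) or linearly decaying ("ramp") transient of amplitude
    ``peak_dff * baseline_f`` lasting ``duration_samples`` samples from
    ``onset_index``.
    """

    n_samples: int = 60
    fs: float = 1.0
    baseline_f: float = 100.0
    background_f: float = 20.0
    peak_dff: float = 0.5
    onset_index: int = 20
    duration_samples: int = 12
    noise_sd: float = 0.0
    shape: str = "boxcar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_index <= 0 or self.onset_index + self.duration_samples > self.n_samples:
            raise ValueError("transient must lie within the trace after a baseline")
        if not self.baseline_f > self.background_f >= 0:
            raise ValueError("require baseline_f > background_f >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.shape not in ("boxcar", "ramp"):
            raise ValueError("shape must be 'boxcar' or 'ramp'")


@dataclass
class TraceTruth:
    """Planted transient amplitude and duration."""

    peak_dff: float
    duration_s: float


def generate_trace(spec: SyntheticTraceSpec):
    """Simulate a fluorescence trace; returns ``(trace, truth)``."""
    rng = np.random.default_rng(spec.seed)
    f = np.full(spec.n_samples, spec.background_f + spec.baseline_f, dtype=float)
    amp = spec.peak_dff * spec.baseline_f
    sl = slice(spec.onset_index, spec.onset_index + spec.duration_samples)
    if spec.shape == "boxcar":
        f[sl] += amp
    else:  # linear decay from the peak at onset back to baseline
        f[sl] += amp * np.linspace(1.0, 1.0 / spec.duration_samples, spec.duration_samples)
    if spec.noise_sd > 0:
        f += spec.noise_sd * rng.standard_normal(spec.n_samples)
    trace = FluorTrace(
        samples=f,
        fs=spec.fs,
        baseline_window=(0, spec.onset_index),
        background=spec.background_f,
    )
    truth = TraceTruth(
        peak_dff=spec.peak_dff, duration_s=spec.duration_samples / spec.fs
    )
    return trace, truth
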