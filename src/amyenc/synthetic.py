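"""Synthetic cohorts: parcellations, feature series, ground truth, images.

Everything downstream of this module treats its outputs exactly as it would
treat real data: a movie-watching session is a feature time series plus a
parcellated BOLD matrix; an affective image set is a stack of RGB images
with normative valence/arousal ratings; and a fixed generator/extractor
pair stands in for the deep image generator and the convolutional feature
extractor, closing the activation-maximization loop at desk scale.

Design of the pieces:

* Ground-truth voxel weights are built from per-region base patterns.  A
  ``distinctness`` dial interpolates between one shared base (0) and
  mutually orthonormal bases (1), so region selectivity of the simulated
  cohort is controlled explicitly.
* Synthetic affective images are mixtures of a constant color field and two
  sinusoidal gratings, one inside the low spatial-frequency band and one
  inside the high band, so their low-level covariates are known by
  construction.
* Ratings are linear in the (standardized) low-level features plus an
  independent latent affect factor, giving the validation regressions both
  confounded and clean signal paths to separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    FeatureTimeSeries,
    GroundTruth,
    ParcellatedBOLD,
    Parcellation,
)
from .hrf import HRFKernel, convolve_truncate

logger = logging.getLogger(__name__)

#: Desk-scale default region sizes (voxel counts).
DESK_REGION_SIZES = {"LB": 18, "CM": 10, "SF": 8, "AStr": 6, "VC": 30, "IT": 20}
#: Study-scale region sizes: amygdala subregions within 29-178 voxels and a
#: bilateral amygdala of 250 voxels, with much larger visual-cortex and
#: inferotemporal control regions.
REAL_REGION_SIZES = {"LB": 112, "CM": 40, "SF": 60, "AStr": 38, "VC": 3064, "IT": 850}

#: Desk-scale default feature dimension (the study-scale analogue is the
#: 4,096-unit fc7 layer; any F is accepted).
DEFAULT_N_FEATURES = 64


def make_parcellation(
    n_voxels_per_region: dict[str, int] | None = None,
    seed: int = 0,
) -> Parcellation:
    """Create a voxel parcellation with the given region sizes.

    Voxel ids are contiguous from 0 and region labels are interleaved in a
    seeded random order (regions are not contiguous blocks, as in a real
    label volume flattened over a mask).
    """
    if n_voxels_per_region is None:
        n_voxels_per_region = dict(DESK_REGION_SIZES)
    labels: list[str] = []
    for region, count in n_voxels_per_region.items():
        if not isinstance(count, (int, np.integer)) or count < 1:
            raise ValueError(f"region {region!r} needs a positive voxel count")
        labels.extend([region] * int(count))
    lab = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rng.shuffle(lab)
    return Parcellation(voxel_ids=np.arange(lab.size), labels=lab)


def make_feature_timeseries(
    T: int,
    F: int = DEFAULT_N_FEATURES,
    latent_rank: int = 8,
    seed: int = 0,
    noise_sd: float = 0.1,
    dt: float = 1.0,
) -> FeatureTimeSeries:
    """Low-rank latent feature series emulating deep-network activations.

    ``X = L @ P + noise``, with ``L`` a T x rank latent trajectory and ``P``
    a rank x F mixing matrix scaled so column variances are near 1.  The
    noise floor (default SD 0.1) makes the matrix full rank while keeping
    the latent structure dominant; set ``noise_sd=0`` for an exactly
    rank-limited matrix.
    """
    if not 1 <= latent_rank <= F:
        raise ValueError("latent_rank must satisfy 1 <= latent_rank <= F")
    if T <= latent_rank:
        raise ValueError("T must exceed latent_rank")
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((T, latent_rank))
    P = rng.standard_normal((latent_rank, F)) / np.sqrt(latent_rank)
    X = L @ P
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal((T, F))
    return FeatureTimeSeries(data=X, dt=dt)


def _region_bases(
    regions: list[str], F: int, distinctness: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Unit-norm base weight pattern per region.

    ``distinctness=0`` returns the same base for every region;
    ``distinctness=1`` returns mutually orthonormal bases.
    """
    if not 0.0 <= distinctness <= 1.0:
        raise ValueError("distinctness must lie in [0, 1]")
    n = len(regions)
    if n + 1 > F:
        raise ValueError(f"F={F} too small for {n} distinct region bases")
    # orthonormal frame: column 0 is the shared base, the rest are
    # region-specific directions orthogonal to it and to each other
    A = rng.standard_normal((F, n + 1))
    Qmat, _ = np.linalg.qr(A)
    shared = Qmat[:, 0]
    bases = {}
    for i, region in enumerate(regions):
        b = (1.0 - distinctness) * shared + distinctness * Qmat[:, i + 1]
        bases[region] = b / np.linalg.norm(b)
    return bases


def make_ground_truth_weights(
    F: int,
    parcellation: Parcellation,
    distinctness: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 0.1,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    latent_rank: int = 8,
) -> GroundTruth:
    """Ground-truth voxel weights with controllable region selectivity.

    Every voxel's weight vector is its region's unit-norm base pattern plus
    a Gaussian jitter vector of expected norm ``jitter_sd`` (i.e. jitter_sd
    is relative to the base norm), scaled by ``amplitude``.  ``noise_sd``
    is stored for the forward simulation.
    """
    if F < 2:
        raise ValueError("F must be >= 2")
    rng = np.random.default_rng(seed)
    regions = parcellation.regions
    bases = _region_bases(regions, F, distinctness, rng)
    jit = jitter_sd / np.sqrt(F)
    W = np.empty((F, parcellation.n_voxels))
    for i, region in enumerate(parcellation.labels):
        W[:, i] = bases[str(region)] + jit * rng.standard_normal(F)
    W *= amplitude
    return GroundTruth(
        W=W,
        parcellation=parcellation,
        noise_sd=noise_sd,
        latent_rank=latent_rank,
        seed=seed,
        region_bases=bases,
    )


def make_cohort_ground_truth(
    F: int,
    parcellation: Parcellation,
    n_subjects: int,
    distinctness: float = 1.0,
    subject_sd: float = 0.15,
    jitter_sd: float = 0.1,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> list[GroundTruth]:
    """Per-subject ground truths sharing one set of population region bases.

    Regions have consistent functional tuning across subjects (the premise
    that makes leave-one-subject-out generalization possible): subject s
    perturbs each population base by a Gaussian vector of expected norm
    ``subject_sd`` (relative to the unit base norm) before adding
    voxel-level jitter of expected norm ``jitter_sd``.
    """
    rng = np.random.default_rng(seed)
    regions = parcellation.regions
    bases = _region_bases(regions, F, distinctness, rng)
    sub = subject_sd / np.sqrt(F)
    jit = jitter_sd / np.sqrt(F)
    truths = []
    for s in range(n_subjects):
        subj_bases = {
            r: b + sub * rng.standard_normal(F) for r, b in bases.items()
        }
        W = np.empty((F, parcellation.n_voxels))
        for i, region in enumerate(parcellation.labels):
            W[:, i] = subj_bases[str(region)] + jit * rng.standard_normal(F)
        W *= amplitude
        truths.append(
            GroundTruth(
                W=W,
                parcellation=parcellation,
                noise_sd=noise_sd,
                latent_rank=0,
                seed=seed,
                region_bases=subj_bases,
            )
        )
    return truths


def simulate_session(
    features: FeatureTimeSeries,
    truth: GroundTruth,
    hrf_kernel: HRFKernel,
    seed: int = 0,
) -> ParcellatedBOLD:
    """Forward-simulate a BOLD session: ``Y = conv(X, h) @ W + noise``.

    Features are causally convolved with the HRF, truncated to the feature
    length, multiplied by the ground-truth weights, and corrupted with
    i.i.d. Gaussian noise of SD ``truth.noise_sd``.
    """
    if features.n_features != truth.n_features:
        raise ValueError(
            f"features have F={features.n_features} but ground truth expects "
            f"F={truth.n_features}"
        )
    if features.n_timepoints < hrf_kernel.samples.size:
        raise ValueError("feature length must be at least the kernel length")
    conv = convolve_truncate(features, hrf_kernel, features.n_timepoints)
    Y = conv.data @ truth.W
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        Y = Y + truth.noise_sd * rng.standard_normal(Y.shape)
    return ParcellatedBOLD(data=Y, parcellation=truth.parcellation, dt=features.dt)


# ---------------------------------------------------------------------------
# Affective image sets
# ---------------------------------------------------------------------------

#: Default generating coefficients for the normative ratings.  Keys map a
#: rating dimension to {predictor: weight}; "affect" is an independent
#: standard-normal latent factor (one per rating dimension), the remaining
#: keys are standardized low-level image features, giving each rating both a
#: clean path (the latent) and a confounded path (the image statistics).
DEFAULT_RATING_COEFFS = {
    "valence": {"affect": 1.0, "power_low": 0.4, "median_r": 0.2},
    "arousal": {"affect": 1.0, "power_high": 0.3},
}

_FEATURE_KEYS = ("median_r", "median_g", "median_b", "power_low", "power_high")


from functools import lru_cache


@lru_cache(maxsize=8)
def _pixel_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return y, x


def _grating(size: int, fx: int, fy: int, phase: float) -> np.ndarray:
    """Unit-amplitude sinusoidal grating with integer frequency (fx, fy)."""
    y, x = _pixel_grid(size)
    return np.sin(2.0 * np.pi * (fx * x + fy * y) / size + phase)


def make_affective_imageset(
    n_images: int,
    coeffs: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    size: int = 128,
    low_freq_radius: int = 3,
    high_freq_radius: int = 30,
):
    """Generate images with known low-level statistics plus normative ratings.

    Each image is a constant RGB field (channel values uniform in
    [0.3, 0.7]) plus two achromatic gratings: one at radial frequency
    ``low_freq_radius`` (inside the low spectral band) and one at
    ``high_freq_radius`` (inside the high band), with amplitudes uniform in
    [0, 0.12] so no pixel clips.  Ratings are linear combinations of the
    image's standardized low-level features and an independent latent
    affect factor, plus Gaussian noise, then standardized to mean 0 / SD 1.

    Returns
    -------
    images : ndarray, shape (n_images, size, size, 3)
    ratings : DataFrame with columns image_id, valence, arousal
    features : DataFrame with the measured low-level features per image
    """
    from .image_features import image_feature_table

    if n_images < 8:
        raise ValueError("n_images must be >= 8")
    if coeffs is None:
        coeffs = DEFAULT_RATING_COEFFS
    rng = np.random.default_rng(seed)

    images = np.empty((n_images, size, size, 3))
    for i in range(n_images):
        base = rng.uniform(0.3, 0.7, size=3)
        img = np.broadcast_to(base, (size, size, 3)).copy()
        for radius in (low_freq_radius, high_freq_radius):
            ang = rng.uniform(0, 2 * np.pi)
            fx = int(round(radius * np.cos(ang)))
            fy = int(round(radius * np.sin(ang)))
            if fx == 0 and fy == 0:
                fx = radius
            amp = rng.uniform(0.0, 0.12)
            img += (amp * _grating(size, fx, fy, rng.uniform(0, 2 * np.pi)))[
                :, :, None
            ]
        images[i] = np.clip(img, 0.0, 1.0)

    features = image_feature_table(images, working_size=size)

    def _zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd < 1e-12:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    zfeat = {k: _zscore(features[k].to_numpy()) for k in _FEATURE_KEYS}
    ratings = {"image_id": features["image_id"]}
    for dim in ("valence", "arousal"):
        cmap = coeffs.get(dim, {})
        r = np.zeros(n_images)
        for key, c in cmap.items():
            if key == "affect":
                r = r + c * rng.standard_normal(n_images)
            elif key in zfeat:
                r = r + c * zfeat[key]
            else:
                raise ValueError(f"unknown rating predictor {key!r}")
        r = r + noise_sd * rng.standard_normal(n_images)
        ratings[dim] = _zscore(r)
    return images, pd.DataFrame(ratings), features


# ---------------------------------------------------------------------------
# Toy generator / extractor pair
# ---------------------------------------------------------------------------


@dataclass
class ToyNetworks:
    """Fixed generator and feature-extractor maps closing the synthesis loop.

    The generator is a random linear decoder from a latent code of length
    ``d_z`` to pixel space followed by a logistic squash into [0, 1] (the
    zero code renders constant mid-gray).  The extractor projects the
    mean-centered pixels through a fixed random matrix and a tanh
    nonlinearity to ``F`` features.  Both maps are deterministic given the
    construction seed and accept batched inputs (leading axes preserved).
    """

    W_gen: np.ndarray
    W_ext: np.ndarray
    height: int
    width: int
    seed: int

    @property
    def d_z(self) -> int:
        return self.W_gen.shape[1]

    @property
    def n_features(self) -> int:
        return self.W_ext.shape[0]

    def generate(self, z: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        z = np.asarray(z, dtype=float)
        img = expit(z @ self.W_gen.T)
        return img.reshape(z.shape[:-1] + (self.height, self.width, 3))

    def extract(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        lead = image.shape[:-3]
        flat = image.reshape(lead + (-1,)) - 0.5
        return np.tanh(flat @ self.W_ext.T)

    def features_from_code(self, z: np.ndarray) -> np.ndarray:
        return self.extract(self.generate(z))

    def save(self, path) -> None:
        np.savez(
            path,
            W_gen=self.W_gen,
            W_ext=self.W_ext,
            height=self.height,
            width=self.width,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "ToyNetworks":
        with np.load(path) as z:
            return cls(
                W_gen=z["W_gen"],
                W_ext=z["W_ext"],
                height=int(z["height"]),
                width=int(z["width"]),
                seed=int(z["seed"]),
            )


def make_toy_networks(
    d_z: int = 12,
    F: int = DEFAULT_N_FEATURES,
    H: int = 64,
    W: int = 64,
    seed: int = 0,
    gen_gain: float = 2.0,
    ext_gain: float = 3.0,
) -> ToyNetworks:
    """Build a seeded generator/extractor pair.

    ``gen_gain`` sets the pre-squash pixel scale (so unit-norm codes span a
    useful part of the logistic range); ``ext_gain`` sets the pre-tanh
    feature scale.
    """
    if d_z < 2:
        raise ValueError("d_z must be >= 2")
    if F < 2:
        raise ValueError("F must be >= 2")
    rng = np.random.default_rng(seed)
    n_pix = H * W * 3
    W_gen = gen_gain * rng.standard_normal((n_pix, d_z)) / np.sqrt(d_z)
    W_ext = ext_gain * rng.standard_normal((F, n_pix)) / np.sqrt(n_pix)
    return ToyNetworks(W_gen=W_gen, W_ext=W_ext, height=H, width=W, seed=seed)


def session_features_from_networks(
    networks: ToyNetworks, T: int, seed: int = 0, dt: float = 1.0
) -> FeatureTimeSeries:
    """A 'movie' feature series: extractor features of T random generator frames.

    Sampling latent codes i.i.d. standard normal and passing them through
    the fixed generator/extractor pair yields a feature series whose
    geometry matches what the synthesis stage can actually reach, closing
    the loop between encoding-model fitting and activation maximization.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((T, networks.d_z))
    return FeatureTimeSeries(data=networks.features_from_code(Z), dt=dt)


def write_images_png(images: np.ndarray, out_dir, prefix: str = "img") -> list[str]:
    """Write a stack of [0, 1] float RGB images as 8-bit PNGs; return paths."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(np.asarray(images)):
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        p = out / f"{prefix}_{i:04d}.png"
        Image.fromarray(arr).save(p)
        paths.append(str(p))
    return paths
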