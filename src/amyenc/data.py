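"""In-memory containers shared across the pipeline.

The pipeline operates on three kinds of object: a stimulus feature time
series sampled at the BOLD acquisition rate, a voxel-labelled BOLD response
matrix, and the parcellation that assigns every voxel to one anatomical
region.  Four amygdala subregions (LB, CM, SF, AStr) compose the composite
amygdala label ``AMY``; visual cortex (VC) and inferotemporal cortex (IT)
serve as control regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four amygdala subregions, in the fixed analysis order.
AMY_SUBREGIONS = ("LB", "CM", "SF", "AStr")
#: Control regions outside the amygdala.
CONTROL_REGIONS = ("VC", "IT")
#: Composite label for the union of the four amygdala subregions.
AMY = "AMY"
#: All seven analysis targets.
ALL_REGIONS = (AMY,) + AMY_SUBREGIONS + CONTROL_REGIONS


@dataclass(frozen=True)
class Parcellation:
    """Assignment of voxels to anatomical regions.

    ``labels[i]`` is the primary region of voxel ``voxel_ids[i]``.  The
    composite region ``AMY`` is derived as the union of LB, CM, SF and AStr
    and is never a primary label.
    """

    voxel_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        vid = np.asarray(self.voxel_ids, dtype=int)
        lab = np.asarray(self.labels)
        if vid.shape != lab.shape or vid.ndim != 1:
            raise ValueError("voxel_ids and labels must be 1-D and aligned")
        if AMY in set(lab.tolist()):
            raise ValueError(f"{AMY!r} is a derived label, not a primary one")
        object.__setattr__(self, "voxel_ids", vid)
        object.__setattr__(self, "labels", lab)

    @property
    def n_voxels(self) -> int:
        return self.voxel_ids.size

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.labels:
            seen.setdefault(str(r))
        return list(seen)

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask over voxels belonging to ``region`` (AMY = union)."""
        if region == AMY:
            return np.isin(self.labels, AMY_SUBREGIONS)
        mask = self.labels == region
        if not mask.any():
            raise ValueError(f"region {region!r} not present in parcellation")
        return mask

    def region_indices(self, region: str) -> np.ndarray:
        """Positional indices of the voxels in ``region``."""
        return np.flatnonzero(self.region_mask(region))

    def region_sizes(self) -> dict[str, int]:
        sizes = {r: int((self.labels == r).sum()) for r in self.regions}
        sizes[AMY] = int(np.isin(self.labels, AMY_SUBREGIONS).sum())
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel_id": self.voxel_ids, "region": self.labels})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Parcellation":
        df = pd.read_csv(path)
        return cls(df["voxel_id"].to_numpy(), df["region"].to_numpy())


@dataclass(frozen=True)
class FeatureTimeSeries:
    """A T x F stimulus feature matrix sampled every ``dt`` seconds."""

    data: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("feature time series must be 2-D (time x feature)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature time series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ParcellatedBOLD:
    """A T x V BOLD response matrix with a voxel parcellation attached."""

    data: np.ndarray
    parcellation: Parcellation
    dt: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("BOLD matrix must be 2-D (time x voxel)")
        if arr.shape[1] != self.parcellation.n_voxels:
            raise ValueError(
                f"BOLD has {arr.shape[1]} voxels but parcellation has "
                f"{self.parcellation.n_voxels}"
            )
        object.__setattr__(self, "data", arr)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def region_data(self, region: str) -> np.ndarray:
        """Time x voxel block restricted to one region."""
        return self.data[:, self.parcellation.region_mask(region)]


@dataclass
class GroundTruth:
    """Known feature-to-voxel weights used to simulate BOLD sessions.

    ``W`` maps the HRF-convolved feature vector at a time point to the noise
    free response of every voxel; ``noise_sd`` scales the additive i.i.d.
    Gaussian measurement noise.
    """

    W: np.ndarray
    parcellation: Parcellation
    noise_sd: float = 1.0
    latent_rank: int = 0
    seed: int = 0
    region_bases: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (feature x voxel)")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains non-finite values")
        if self.W.shape[1] != self.parcellation.n_voxels:
            raise ValueError("W column count must equal voxel count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def region_mean_weights(self, region: str) -> np.ndarray:
        """Mean weight vector over the voxels of ``region``."""
        return self.W[:, self.parcellation.region_mask(region)].mean(axis=1)
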