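"""Release-state classification of probe molecules.

Each probe's distance-to-nanoparticle time series is reduced to a single
dispersion feature (its sample standard deviation) and the features are
clustered with k-means (k = 3).  Clusters are named by ascending
centroid: the tightest is *immobile*, then *released*, then *escaped*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from memtk.chain_metrics import center_of_mass
from memtk.core_model.cell import minimum_image_displacement
from memtk.core_model.model import Topology

CLASS_ORDER = ("immobile", "released", "escaped")


@dataclass
class ReleaseClassification:
    labels: np.ndarray  # per molecule, values in CLASS_ORDER
    features: np.ndarray  # dispersion (nm) per molecule
    centroids: np.ndarray  # ascending, length k

    def to_dataframe(self):
        import pandas as pd

        order = {c: i for i, c in enumerate(CLASS_ORDER)}
        return pd.DataFrame(
            {
                "molecule": np.arange(len(self.labels)),
                "feature_nm": self.features,
                "label": self.labels,
                "centroid_nm": self.centroids[[order[str(l)] for l in self.labels]],
            }
        )


def distance_series(frames, topology: Topology, np_group, molecules) -> tuple[np.ndarray, np.ndarray]:
    """Periodic COM-COM distance of each molecule to the nanoparticle.

    Returns (times, series) with series shaped (n_molecules, n_frames).
    """
    np_group = np.asarray(np_group, dtype=int)
    molecules = [np.asarray(m, dtype=int) for m in molecules]
    if len(np_group) == 0 or not molecules:
        raise ValueError("nanoparticle group and molecules must be non-empty")
    frames = list(frames)
    if not frames:
        raise ValueError("empty trajectory")
    times = np.asarray([fr.time for fr in frames])
    out = np.empty((len(molecules), len(frames)))
    for k, fr in enumerate(frames):
        com_np = center_of_mass(fr.positions, np_group, topology.masses, fr.cell)
        for i, mol in enumerate(molecules):
            com_m = center_of_mass(fr.positions, mol, topology.masses, fr.cell)
            d = minimum_image_displacement(com_np, com_m, fr.cell)
            out[i, k] = np.linalg.norm(d)
    return times, out


def release_feature(series: np.ndarray) -> np.ndarray:
    """Sample standard deviation (ddof = 1) of each molecule's series."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] < 2:
        raise ValueError("series must have length >= 2")
    return series.std(axis=1, ddof=1)


def classify_release(
    features: np.ndarray, k: int = 3, seed: int = 0, restarts: int = 10
) -> ReleaseClassification:
    """k-means on the 1-D dispersion feature; labels by ascending centroid."""
    features = np.asarray(features, dtype=float).ravel()
    if len(features) < k:
        raise ValueError(f"need at least {k} molecules, got {len(features)}")
    if len(np.unique(features)) < k:
        raise ValueError(
            f"only {len(np.unique(features))} distinct feature values; reduce k"
        )
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(features[:, None])
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)
    names = list(CLASS_ORDER[:k]) if k <= len(CLASS_ORDER) else [f"c{i}" for i in range(k)]
    name_of = {int(order[i]): names[i] for i in range(k)}
    labels = np.array([name_of[int(c)] for c in raw], dtype=object)
    return ReleaseClassification(labels, features, np.sort(centroids))
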