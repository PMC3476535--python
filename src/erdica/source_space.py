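"""Component-level source analysis: scalp maps, artifact triage, clustering.

Each independent component carries a scalp map (mixing column mapped back
through the PCA reduction), an equivalent-dipole fit, and a class label:

* ``rejected_rv`` -- the dipole explains less than 85% of the scalp-map
  variance (residual variance > 0.15);
* ``ocular``    -- anterior-inferior dipole with strongly low-frequency
  activation spectrum (blink-dominated);
* ``muscular``  -- dipole outside the brain sphere with rising high-band
  (40-100 Hz) power, the electromyographic signature;
* ``cortical``  -- everything else.

Cortical components from all subjects are clustered with k-means on a
feature vector that concatenates z-scored dipole coordinates (weight 3)
and z-scored 10-dimensional PCA scores of the scalp maps (weight 1),
after interpolating every map to a shared spherical grid so subjects with
different retained-channel subsets become comparable.  Clusters containing
components from at least 75% of subjects (6 of 8 in the reference
protocol) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import RBFInterpolator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .headmodel import DipoleFit, SphereModel, fibonacci_scalp_montage, fit_dipole

__all__ = ["ComponentRecord", "ComponentCluster", "classify_component",
           "make_component_records", "cluster_components"]


@dataclass
class ComponentRecord:
    """One independent component of one subject's decomposition."""

    subject_id: str
    model_id: int
    component_index: int
    scalp_map: np.ndarray               # (n_retained_channels,)
    electrode_positions: np.ndarray     # matching (n, 3)
    dipole: DipoleFit | None = None
    label: str = "unclassified"


@dataclass
class ComponentCluster:
    members: list
    centroid: np.ndarray
    subject_count: int
    retained: bool


def classify_component(record: ComponentRecord, activation: np.ndarray, fs: float,
                       sphere: SphereModel | None = None, rv_limit: float = 0.15,
                       ) -> str:
    """Label a component as rejected_rv / ocular / muscular / cortical."""
    sphere = sphere or SphereModel()
    if record.dipole is None:
        raise ValueError("component has no dipole fit")
    if record.dipole.residual_variance > rv_limit:
        return "rejected_rv"
    x, y, z = record.dipole.location
    f, p = sps.welch(np.asarray(activation, dtype=float), fs=fs,
                     nperseg=min(int(2 * fs), len(activation)))
    if y > 0.8 * sphere.radius and z < 0:
        low = p[(f >= 1) & (f <= 4)].mean()
        mid = p[(f > 4) & (f <= 40)].mean()
        if mid > 0 and low / mid > 2.0:
            return "ocular"
    if np.linalg.norm(record.dipole.location) > sphere.brain_radius:
        band = (f >= 40) & (f <= min(100, f.max()))
        if band.sum() >= 3:
            slope = np.polyfit(f[band], np.log10(p[band] + 1e-30), 1)[0]
            if slope > 0:
                return "muscular"
    return "cortical"


def make_component_records(mixica, subject_id: str, electrode_positions: np.ndarray,
                           activations: np.ndarray | None = None, fs: float = 512.0,
                           sphere: SphereModel | None = None,
                           classify: bool = True) -> list:
    """Dipole-fit and classify every component of every mixture model.

    ``activations`` (n_models, n_components, n_samples) are needed only for
    the spectral artifact rules; without them components are classified on
    dipole criteria alone (ocular/muscular spectral gates default to
    cortical).
    """
    sphere = sphere or SphereModel()
    records = []
    for h in range(mixica.n_models):
        maps = mixica.scalp_maps(h)
        for i in range(maps.shape[1]):
            rec = ComponentRecord(subject_id=subject_id, model_id=h,
                                  component_index=i, scalp_map=maps[:, i],
                                  electrode_positions=electrode_positions)
            rec.dipole = fit_dipole(maps[:, i], electrode_positions, sphere)
            if classify:
                if activations is not None:
                    act = activations[h][i]
                    rec.label = classify_component(rec, act, fs, sphere)
                else:
                    rec.label = ("rejected_rv"
                                 if rec.dipole.residual_variance > 0.15 else "cortical")
            records.append(rec)
    return records


def _interp_to_grid(record: ComponentRecord, grid: np.ndarray) -> np.ndarray:
    """Thin-plate RBF interpolation of a scalp map onto the common grid."""
    interp = RBFInterpolator(record.electrode_positions, record.scalp_map,
                             kernel="thin_plate_spline", smoothing=1e-8)
    v = interp(grid)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def cluster_components(records, k: int = 10, seed: int = 0,
                       location_weight: float = 3.0, map_weight: float = 1.0,
                       n_map_pcs: int = 10, n_grid: int = 64,
                       sphere: SphereModel | None = None,
                       n_init: int = 20) -> list:
    """Weighted k-means clustering of cortical components across subjects.

    Feature vector per component: z-scored dipole (x, y, z) times
    ``location_weight``, concatenated with z-scored PCA scores (up to
    ``n_map_pcs``) of the grid-interpolated scalp maps times ``map_weight``.
    Returns :class:`ComponentCluster` objects sorted by descending subject
    count; ``retained`` marks clusters with components from at least 75% of
    the subjects.
    """
    records = [r for r in records if r.label in ("cortical", "unclassified")]
    # canonical ordering makes the partition invariant to input order
    records.sort(key=lambda r: (r.subject_id, r.model_id, r.component_index))
    if len(records) < k:
        raise ValueError(f"need at least k={k} cortical components, got {len(records)}")
    sphere = sphere or SphereModel()
    grid = fibonacci_scalp_montage(n_grid, sphere)

    locs = np.array([r.dipole.location for r in records])
    maps = np.array([_interp_to_grid(r, grid) for r in records])
    n_pcs = min(n_map_pcs, maps.shape[0] - 1, maps.shape[1])
    scores = PCA(n_components=n_pcs, random_state=0).fit_transform(maps)

    def zscore(a):
        sd = a.std(axis=0)
        return (a - a.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    X = np.hstack([location_weight * zscore(locs), map_weight * zscore(scores)])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)

    n_subjects = len({r.subject_id for r in records})
    need = int(np.ceil(0.75 * n_subjects))
    clusters = []
    for c in range(k):
        members = [r for r, lab in zip(records, km.labels_) if lab == c]
        if not members:
            continue
        centroid = np.mean([m.dipole.location for m in members], axis=0)
        subj = len({m.subject_id for m in members})
        clusters.append(ComponentCluster(members=members, centroid=centroid,
                                         subject_count=subj,
                                         retained=subj >= need))
    clusters.sort(key=lambda c: (-c.subject_count, -len(c.members)))
    return clusters
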