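"""Structural connectivity: I/O, normalization, homotopic augmentation,
region selection, and a synthetic connectome generator.

Connectomes are square symmetric matrices with zero diagonal and weights
in [0, 1] (DTI fiber counts normalized by their maximum).  Matrices are
stored as delimited text with region labels as header/index.  The
hemisphere ordering convention is mirror-symmetric: region i and region
N-1-i are homologs, so homotopic (inter-hemispheric) connections, which
DTI tractography underestimates, live on the matrix anti-diagonal.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Connectome", "RegionSelection", "load_matrix", "save_matrix",
    "normalize_sc", "add_homotopic", "select_regions",
    "synthetic_connectome", "aal90_labels", "region_table",
]


@dataclass
class Connectome:
    """Symmetric weighted connectivity with region labels.

    Invariants (checked on construction): square, symmetric, zero
    diagonal, weights in [0, 1].
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if np.any(~np.isfinite(w)):
            raise ValueError("connectome contains non-finite entries")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("connectome must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("connectome diagonal must be zero")
        if w.min() < 0 or w.max() > 1.0 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w
        if not self.labels:
            self.labels = [f"R{i}" for i in range(w.shape[0])]
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix order")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class RegionSelection:
    """A kept-label subset tagged by modality ('EEG' keeps 82 areas, 'fMRI' all 90)."""

    keep: list[str]
    modality: str = ""


def region_table() -> pd.DataFrame:
    """The AAL90 region table (45 bilateral areas: name, abbreviation, fmri_only)."""
    with importlib.resources.files("jansenrit.data").joinpath("aal90_regions.csv").open() as fh:
        return pd.read_csv(fh)


def aal90_labels() -> list[str]:
    """90 region labels in mirror-symmetric order: left hemisphere first
    (suffix .L), then the right hemisphere reversed (suffix .R), so that
    homologs sit on the anti-diagonal."""
    ab = region_table()["abbreviation"].tolist()
    return [f"{x}.L" for x in ab] + [f"{x}.R" for x in reversed(ab)]


def eeg_region_selection() -> RegionSelection:
    """The 82-area EEG subset: cortex plus hippocampus and amygdala
    (drops caudate, putamen, pallidum and thalamus bilaterally)."""
    tab = region_table()
    drop = set(tab.loc[tab["fmri_only"] == 1, "abbreviation"])
    keep = [lab for lab in aal90_labels() if lab.rsplit(".", 1)[0] not in drop]
    return RegionSelection(keep, modality="EEG")


def load_matrix(path, labels: bool = True, normalize: bool = False) -> Connectome:
    """Read a delimited-text square matrix; labels from header/index if present.

    ``normalize=True`` rescales raw (e.g. fiber-count) weights by their
    global maximum before the [0, 1] invariant is enforced."""
    if labels:
        df = pd.read_csv(path, index_col=0)
        try:
            w = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric entries in {path}") from exc
        labs = [str(c) for c in df.columns]
    else:
        w = np.loadtxt(path, delimiter=",")
        labs = []
    if normalize:
        return normalize_sc(w, labels=labs)
    return Connectome(w, labs)


def save_matrix(conn: Connectome, path) -> None:
    pd.DataFrame(conn.weights, index=conn.labels, columns=conn.labels).to_csv(path)


def normalize_sc(conn, labels: list[str] | None = None) -> Connectome:
    """Scale weights into [0, 1] by the global maximum.

    Accepts a :class:`Connectome` (idempotent: its weights are already in
    [0, 1] and only the maximum moves to 1) or a raw nonnegative array of
    e.g. fiber counts.  A zero matrix passes through unchanged.
    """
    if isinstance(conn, Connectome):
        w, labs, note = conn.weights, list(conn.labels), conn.note
    else:
        w = np.asarray(conn, dtype=float)
        labs, note = list(labels or []), ""
    if w.min() < 0:
        raise ValueError("negative weights cannot be normalized to [0, 1]")
    m = w.max()
    return Connectome(w / m if m > 0 else w.copy(), labs,
                      note=(note + " normalized").strip())


def add_homotopic(conn: Connectome, weight: float | None = None) -> Connectome:
    """Set anti-diagonal (homotopic) entries to at least ``weight``.

    Requires the mirror-symmetric hemisphere ordering (homolog of region
    i is region N-1-i).  ``weight=None`` uses the matrix maximum (1.0
    for a normalized matrix).  Idempotent; the diagonal is untouched.
    """
    n = conn.n
    if n % 2:
        raise ValueError("homotopic augmentation needs an even number of regions")
    if weight is None:
        weight = float(conn.weights.max()) if conn.weights.max() > 0 else 1.0
    if not 0.0 <= weight <= 1.0:
        raise ValueError("homotopic weight must lie in [0, 1]")
    w = conn.weights.copy()
    for i in range(n):
        j = n - 1 - i
        if i != j:
            w[i, j] = max(w[i, j], weight)
    return Connectome(w, list(conn.labels), note=(conn.note + " homotopic").strip())


def select_regions(conn: Connectome, selection: RegionSelection) -> Connectome:
    """Submatrix on the kept labels, preserving the connectome's order."""
    unknown = set(selection.keep) - set(conn.labels)
    if unknown:
        raise KeyError(f"unknown region labels: {sorted(unknown)}")
    keep = set(selection.keep)
    idx = [i for i, lab in enumerate(conn.labels) if lab in keep]
    w = conn.weights[np.ix_(idx, idx)]
    return Connectome(w, [conn.labels[i] for i in idx],
                      note=(conn.note + f" selected:{selection.modality}").strip())


def synthetic_connectome(n: int, n_modules: int = 2, intra_density: float = 0.8,
                         inter_density: float = 0.2, seed: int = 0,
                         binary: bool = False) -> Connectome:
    """Random modular connectome with mirrored hemispheres.

    One hemisphere of ``n//2`` regions is drawn with ``n_modules``
    contiguous modules (edge probability ``intra_density`` within and
    ``inter_density`` between modules, uniform weights), then mirrored so
    region i and region n-1-i are homologs and :func:`add_homotopic`
    applies.  Deterministic per seed.
    """
    if n < 2 or n % 2:
        raise ValueError("n must be an even integer >= 2")
    for d in (intra_density, inter_density):
        if not 0.0 <= d <= 1.0:
            raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h = n // 2
    module = np.array([min(i * n_modules // h, n_modules - 1) for i in range(h)])
    hemi = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            dens = intra_density if module[i] == module[j] else inter_density
            if rng.random() < dens:
                hemi[i, j] = hemi[j, i] = 1.0 if binary else rng.uniform(0.2, 1.0)
    # mirror: right hemisphere is a reversed copy; weak uniform inter-hemispheric links
    w = np.zeros((n, n))
    w[:h, :h] = hemi
    w[h:, h:] = hemi[::-1, ::-1]
    for i in range(h):
        for j in range(h):
            if rng.random() < inter_density / 2.0:
                val = 1.0 if binary else rng.uniform(0.05, 0.3)
                w[i, n - 1 - j] = val
                w[n - 1 - j, i] = val
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return Connectome(w, note=f"synthetic(n={n},seed={seed})")
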