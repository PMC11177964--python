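"""Fixed-length topological feature vectors for wild-type/mutant pairs.

For every configured (site type, element pair) subset the filtration is
scanned on a fixed grid; at each grid value the (persistent) Laplacian
spectrum is summarized into seven statistics plus a presence flag:

    harmonic multiplicity (the Betti number), then min / max / mean /
    standard deviation / sum / variance of the non-harmonic eigenvalues,
    and a flag marking whether any non-harmonic eigenvalue existed.

Dimension-0 blocks come from a Vietoris–Rips filtration over the modified
(cross-group) distance by default; dimension-1 and -2 blocks come from the
Alpha complex of the same point cloud with same-group simplices pruned.
A feature vector is the concatenation of the wild-type block, the mutant
block, and their difference (mutant − wild-type), the latter giving the
regressor an explicit delta channel for the difference quantity ΔΔG.

An optional plug-in slot lets callers append externally computed per-residue
embeddings (e.g. language-model features); nothing of that kind is computed
here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import sites as _sites
from .filtration import (
    DEFAULT_GRID_DIM0,
    DEFAULT_GRID_DIM12,
    build_alpha,
    build_rips,
    prune_cross_only,
    snapshot,
)
from .laplacian import (
    combinatorial_laplacian,
    persistent_laplacian,
    spectrum,
)
from .structure_io import AA1_TO_3, Atom, MutationSpec, Structure

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "spectral_statistics",
    "filtration_features",
    "assemble_features",
    "build_mutant",
    "LaplacianFeaturizer",
    "STATISTIC_NAMES",
]

STATISTIC_NAMES = (
    "betti", "nz_min", "nz_max", "nz_mean", "nz_std", "nz_sum", "nz_var", "nz_present",
)

#: Unordered element pairs over the heavy-atom groups used for featurization.
DEFAULT_ELEMENT_PAIRS = (
    ("C", "C"), ("C", "N"), ("C", "O"), ("N", "N"), ("N", "O"), ("O", "O"),
)


@dataclass(frozen=True)
class FeatureConfig:
    """Declarative description of one feature schema.

    ``persistence_steps`` sets p as a number of grid steps (0 = plain
    combinatorial Laplacian at each grid value). ``dim0_mode`` selects
    whether the dimension-0 Rips filtration uses the modified cross-group
    distance (``"mod"``) or the raw Euclidean distance.
    """

    element_pairs: tuple[tuple[str, str], ...] = DEFAULT_ELEMENT_PAIRS
    site_types: tuple[str, ...] = ("mutation", "interface")
    r_neighborhood: float = _sites.DEFAULT_NEIGHBORHOOD_RADIUS
    r_binding: float = _sites.DEFAULT_BINDING_RADIUS
    grid_dim0: tuple[float, ...] = tuple(DEFAULT_GRID_DIM0)
    grid_dim12: tuple[float, ...] = tuple(DEFAULT_GRID_DIM12)
    dims: tuple[int, ...] = (0, 1, 2)
    dim0_mode: str = "mod"
    persistence_steps: int = 1

    def __post_init__(self) -> None:
        if self.dim0_mode not in ("mod", "euclidean"):
            raise ValueError("dim0_mode must be 'mod' or 'euclidean'")
        if self.persistence_steps < 0:
            raise ValueError("persistence_steps must be >= 0")
        for st in self.site_types:
            if st not in ("mutation", "interface"):
                raise ValueError(f"unknown site type {st!r}")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]

    def schema(self) -> list[str]:
        """Descriptor names for one structure block, in vector order."""
        names: list[str] = []
        for site in self.site_types:
            for e1, e2 in self.element_pairs:
                for k in self.dims:
                    grid = self.grid_dim0 if k == 0 else self.grid_dim12
                    for t in grid:
                        for stat in STATISTIC_NAMES:
                            names.append(f"{site}|{e1}{e2}|k{k}|t{t:g}|{stat}")
        return names


@dataclass(frozen=True)
class FeatureVector:
    """Assembled wt/mut/difference feature vector with its schema."""

    values: np.ndarray
    schema: tuple[str, ...]
    config_hash: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.schema),):
            raise ValueError("value length does not match schema")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature value")


def spectral_statistics(spec) -> np.ndarray:
    """Seven summary statistics of a spectrum plus a presence flag."""
    nz = spec.non_harmonic
    betti = float(spec.harmonic.size)
    if nz.size == 0:
        return np.array([betti, 0, 0, 0, 0, 0, 0, 0.0])
    return np.array([
        betti, nz.min(), nz.max(), nz.mean(), nz.std(), nz.sum(), nz.var(), 1.0,
    ])


# ---------------------------------------------------------------------------
# subset pairs


def _labeled_subset_pair(
    structure: Structure,
    mut: MutationSpec,
    config: FeatureConfig,
    site_type: str,
    e1: str,
    e2: str,
) -> tuple[list[Atom], list[str]]:
    """Atoms of one (site, element-pair) subset with their group labels.

    Mutation-centric pairs oppose (mutation-site atoms of element e1) to
    (neighborhood-minus-site atoms of element e2); interface pairs oppose
    the two partners' binding-site atoms. The two groups play the role of
    P1/P2 in the modified-distance rule.
    """
    if site_type == "mutation":
        a_m = _sites.select_mutation_site(structure, mut)
        a_mn = _sites.select_neighborhood(structure, mut, config.r_neighborhood)
        site_set = set(a_m)
        ga = _sites.filter_by_element(a_m, [e1])
        gb = _sites.filter_by_element([a for a in a_mn if a not in site_set], [e2])
        labels = ["M"] * len(ga) + ["N"] * len(gb)
    else:
        ga = _sites.filter_by_element(
            _sites.select_binding_site(structure, "P1", config.r_binding), [e1]
        )
        gb = _sites.filter_by_element(
            _sites.select_binding_site(structure, "P2", config.r_binding), [e2]
        )
        labels = ["P1"] * len(ga) + ["P2"] * len(gb)
    return ga + gb, labels


def _grid_spectra_stats(
    atoms: list[Atom],
    labels: list[str],
    k: int,
    config: FeatureConfig,
) -> np.ndarray:
    """Statistics along the grid for one subset and one dimension."""
    grid = np.asarray(config.grid_dim0 if k == 0 else config.grid_dim12)
    out = np.zeros((len(grid), len(STATISTIC_NAMES)))
    if len(atoms) == 0:
        return out.ravel()
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 0.0
    p = config.persistence_steps * step
    if k == 0:
        label_of = dict(zip(atoms, labels))
        dist = _sites.pairwise_distances(
            atoms, atoms, mode=config.dim0_mode,
            grouping=(label_of.__getitem__ if config.dim0_mode == "mod" else None),
        )
        cx = build_rips(dist, max_dim=1, max_filtration=float(grid[-1]) + p)
    else:
        if len(atoms) < 2:
            cx = None
        else:
            coords = np.array([a.coords for a in atoms])
            cx = prune_cross_only(build_alpha(coords, max_dim=2), dict(enumerate(labels)))
    if cx is None:
        return out.ravel()
    for i, t in enumerate(grid):
        snap_t = snapshot(cx, float(t))
        if snap_t.n_simplices(k) == 0:
            continue
        if p > 0:
            lap = persistent_laplacian(snap_t, snapshot(cx, float(t) + p), k)
        else:
            lap = combinatorial_laplacian(snap_t, k)
        out[i] = spectral_statistics(spectrum(lap, k, float(t), p))
    return out.ravel()


def filtration_features(
    structure: Structure,
    mut: MutationSpec,
    config: FeatureConfig,
) -> np.ndarray:
    """One structure's full feature block, in :meth:`FeatureConfig.schema` order."""
    blocks = []
    for site in config.site_types:
        for e1, e2 in config.element_pairs:
            atoms, labels = _labeled_subset_pair(structure, mut, config, site, e1, e2)
            for k in config.dims:
                blocks.append(_grid_spectra_stats(atoms, labels, k, config))
    return np.concatenate(blocks) if blocks else np.zeros(0)


def build_mutant(structure: Structure, mut: MutationSpec) -> Structure:
    """Fallback mutant builder: side-chain truncation at the mutated residue.

    Keeps backbone plus CB (CB dropped when mutating to glycine) and renames
    the residue; no repacking or side-chain reconstruction is attempted.
    Intended for testing and for users without modelled mutant structures.
    """
    target = AA1_TO_3[mut.mut_aa]
    keep_names = {"N", "CA", "C", "O"} | ({"CB"} if mut.mut_aa != "G" else set())
    atoms: list[Atom] = []
    found = False
    for a in structure.atoms:
        if a.chain == mut.chain and a.res_seq == mut.res_seq:
            found = True
            if a.name in keep_names:
                atoms.append(dc_replace(a, res_name=target))
        else:
            atoms.append(a)
    if not found:
        raise KeyError(f"no residue {mut.res_seq} on chain {mut.chain}")
    return Structure(f"{structure.id}_{mut.code}", atoms, dict(structure.partition))


def assemble_features(
    wt: Structure,
    mutant: Structure,
    mut: MutationSpec,
    config: FeatureConfig,
    extra: np.ndarray | None = None,
) -> FeatureVector:
    """Concatenate wt block, mutant block and their difference.

    ``extra`` is the plug-in slot for externally computed embeddings; it is
    appended verbatim with generic descriptor names.
    """
    wt_block = filtration_features(wt, mut, config)
    # in the mutant the residue already carries the new identity
    mut_spec = MutationSpec(mut.mut_aa, mut.chain, mut.res_seq, mut.wt_aa)
    mut_block = filtration_features(mutant, mut_spec, config)
    if wt_block.shape != mut_block.shape:
        raise ValueError("wt and mutant feature blocks disagree in shape")
    base = config.schema()
    values = np.concatenate([wt_block, mut_block, mut_block - wt_block])
    schema = (
        [f"wt|{s}" for s in base]
        + [f"mut|{s}" for s in base]
        + [f"diff|{s}" for s in base]
    )
    if extra is not None:
        extra = np.asarray(extra, dtype=float).ravel()
        values = np.concatenate([values, extra])
        schema += [f"extra|{i}" for i in range(extra.size)]
    return FeatureVector(values, tuple(schema), config.config_hash)


class LaplacianFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer from (wt, mutant, mutation) triples to features.

    ``transform`` accepts an iterable of ``(wt_structure, mutant_structure,
    MutationSpec)`` triples (``mutant_structure`` may be None, in which case
    the side-chain-truncation fallback is used) and returns a dense feature
    matrix. The transformer is stateless: ``fit`` only freezes the schema.
    """

    def __init__(
        self,
        element_pairs=DEFAULT_ELEMENT_PAIRS,
        site_types=("mutation", "interface"),
        r_neighborhood=_sites.DEFAULT_NEIGHBORHOOD_RADIUS,
        r_binding=_sites.DEFAULT_BINDING_RADIUS,
        grid_dim0=tuple(DEFAULT_GRID_DIM0),
        grid_dim12=tuple(DEFAULT_GRID_DIM12),
        dims=(0, 1, 2),
        dim0_mode="mod",
        persistence_steps=1,
    ):
        self.element_pairs = element_pairs
        self.site_types = site_types
        self.r_neighborhood = r_neighborhood
        self.r_binding = r_binding
        self.grid_dim0 = grid_dim0
        self.grid_dim12 = grid_dim12
        self.dims = dims
        self.dim0_mode = dim0_mode
        self.persistence_steps = persistence_steps

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            element_pairs=tuple(tuple(p) for p in self.element_pairs),
            site_types=tuple(self.site_types),
            r_neighborhood=self.r_neighborhood,
            r_binding=self.r_binding,
            grid_dim0=tuple(self.grid_dim0),
            grid_dim12=tuple(self.grid_dim12),
            dims=tuple(self.dims),
            dim0_mode=self.dim0_mode,
            persistence_steps=self.persistence_steps,
        )

    def fit(self, X=None, y=None):
        cfg = self._config()
        base = cfg.schema()
        self.feature_names_ = (
            [f"wt|{s}" for s in base]
            + [f"mut|{s}" for s in base]
            + [f"diff|{s}" for s in base]
        )
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit()
        cfg = self._config()
        rows = []
        for wt, mutant, mut in X:
            if mutant is None:
                mutant = build_mutant(wt, mut)
            rows.append(assemble_features(wt, mutant, mut, cfg).values)
        return np.array(rows).reshape(len(rows), -1)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.array(self.feature_names_, dtype=object)
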