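"""Model interpretation: discriminative ROIs, frequency bands, feature-block Shapley.

Region importance reads the first row-spanning convolution (the 32 x R kernel
bank): summing absolute kernel weights over the 32 filters yields one
nonnegative number per ROI column.  For the dynamic branch this is the
convolution *after* channel compression.  Band importance is the absolute
value of the Q channel-compression weights of the dynamic branch.

Block-level Shapley values treat the three feature groups (SRS, static-deep,
dynamic-deep) as players in the classic allocation

    φ_i = Σ_{T ⊆ S∖{i}} |T|! (|S|−|T|−1)! / |S|! · [f(x_{T∪{i}}) − f(x_T)]

evaluated exactly over all 2³ coalitions on the SVM decision value; features
outside a coalition are replaced by the training-set means (the declared
baseline).  Efficiency, dummy and symmetry hold exactly by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .connectivity import FrequencyGrid
from .feature_cnn import CnnBranchExtractor, TrainedExtractor
from .fusion import FEATURE_SLICES, FeatureBundle, HybridConnectomeClassifier
from .io_core import SubjectRecord, ValidationError, atlas_labels

__all__ = [
    "RegionRanking",
    "BandRanking",
    "GroupShapley",
    "rank_regions",
    "rank_bands",
    "group_shapley",
    "explain_report",
]

_BLOCKS = ("srs", "static", "dynamic")


@dataclass(frozen=True)
class RegionRanking:
    branch: str
    importance: np.ndarray  # R nonnegative reals
    top_indices: tuple[int, ...]
    labels: tuple[str, ...]


@dataclass(frozen=True)
class BandRanking:
    importance: np.ndarray  # Q nonnegative reals
    band_edges: tuple[tuple[float, float], ...]
    top_indices: tuple[int, ...]


@dataclass(frozen=True)
class GroupShapley:
    subject_id: str
    phi: dict[str, float]  # signed, per block
    phi_abs: dict[str, float]
    f_x: float
    f_baseline: float
    baseline: str = "training-set feature means"


def _weight_matrix(model: TrainedExtractor | CnnBranchExtractor, key: str) -> np.ndarray:
    if isinstance(model, TrainedExtractor):
        return np.asarray(model.state[key])
    if isinstance(model, CnnBranchExtractor):
        return np.asarray(model.net_.W[key])
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def _kind_of(model: TrainedExtractor | CnnBranchExtractor) -> str:
    if isinstance(model, TrainedExtractor):
        return model.architecture.kind
    return model.kind


def _ranked(importance: np.ndarray, k: int, ascending_ties: bool = True) -> tuple[int, ...]:
    # sort by descending importance; ties broken by the lower index
    idx = np.lexsort((np.arange(importance.size), -importance))
    return tuple(int(i) for i in idx[:k])


def rank_regions(
    model: TrainedExtractor | CnnBranchExtractor,
    branch: str,
    top_k: int = 10,
) -> RegionRanking:
    """ROI importance from the 32 x R row-convolution kernel bank of ``branch``."""
    if branch not in ("static", "dynamic"):
        raise ValidationError(f"branch must be 'static' or 'dynamic', got {branch!r}")
    if _kind_of(model) != branch:
        raise ValidationError(
            f"model is a {_kind_of(model)} branch; cannot rank as {branch}"
        )
    w1 = _weight_matrix(model, "W1")  # (32, R), bias excluded
    importance = np.abs(w1).sum(axis=0)
    r = importance.size
    top = _ranked(importance, min(top_k, r))
    labels = atlas_labels(r)
    return RegionRanking(
        branch=branch,
        importance=importance,
        top_indices=top,
        labels=tuple(labels[i] for i in top),
    )


def rank_bands(
    model: TrainedExtractor | CnnBranchExtractor,
    grid: FrequencyGrid,
    top_k: int = 10,
) -> BandRanking:
    """Frequency-band importance from the dynamic branch's compression weights."""
    if _kind_of(model) != "dynamic":
        raise ValidationError("band ranking needs the dynamic branch (has no compression "
                              "layer in the static branch)")
    wc = _weight_matrix(model, "Wc")
    importance = np.abs(wc)
    q = importance.size
    if q != grid.n_bands:
        raise ValidationError(
            f"model has {q} compression weights but grid has {grid.n_bands} bands"
        )
    top = _ranked(importance, min(top_k, q))
    return BandRanking(
        importance=importance,
        band_edges=tuple(grid.band_edges(i) for i in range(q)),
        top_indices=top,
    )


def group_shapley(
    classifier: HybridConnectomeClassifier | Callable[[np.ndarray], np.ndarray],
    bundle: FeatureBundle,
    baseline: np.ndarray,
) -> GroupShapley:
    """Exact Shapley values of the three feature blocks on the decision value.

    ``classifier`` is either a fitted :class:`HybridConnectomeClassifier` (its
    SVM decision function is used) or any callable mapping an (m, 37) feature
    matrix to m real values.  ``baseline`` is the 37-vector substituted for
    blocks outside a coalition.
    """
    baseline = np.asarray(baseline, dtype=float).reshape(-1)
    if baseline.size != bundle.vector.size:
        raise ValidationError(
            f"baseline has {baseline.size} entries, bundle has {bundle.vector.size}"
        )
    if isinstance(classifier, HybridConnectomeClassifier):
        f = classifier.decision_from_raw
    else:
        f = classifier

    coalitions = list(
        itertools.chain.from_iterable(
            itertools.combinations(_BLOCKS, r) for r in range(len(_BLOCKS) + 1)
        )
    )
    rows = np.tile(baseline, (len(coalitions), 1))
    for ci, coalition in enumerate(coalitions):
        for block in coalition:
            sl = FEATURE_SLICES[block]
            rows[ci, sl] = bundle.vector[sl]
    values = dict(zip(coalitions, np.asarray(f(rows), dtype=float)))

    s = len(_BLOCKS)
    phi: dict[str, float] = {}
    for block in _BLOCKS:
        others = tuple(b for b in _BLOCKS if b != block)
        total = 0.0
        for r in range(len(others) + 1):
            for team in itertools.combinations(others, r):
                weight = math.factorial(len(team)) * math.factorial(s - len(team) - 1) / math.factorial(s)
                with_i = tuple(b for b in _BLOCKS if b in team or b == block)
                total += weight * (values[with_i] - values[team])
        phi[block] = total
    return GroupShapley(
        subject_id=bundle.subject_id,
        phi=phi,
        phi_abs={k: abs(v) for k, v in phi.items()},
        f_x=values[tuple(_BLOCKS)],
        f_baseline=values[()],
    )


def explain_report(
    static_model: TrainedExtractor | CnnBranchExtractor,
    dynamic_model: TrainedExtractor | CnnBranchExtractor,
    classifier: HybridConnectomeClassifier,
    records: Sequence[SubjectRecord],
    grid: FrequencyGrid,
    top_k: int = 10,
) -> dict:
    """JSON-serializable interpretability report.

    Contains the region ranking of both branches, the band ranking, and one
    Shapley triple per requested subject.  Deterministic given its inputs.
    """
    regions = {
        "static": rank_regions(static_model, "static", top_k),
        "dynamic": rank_regions(dynamic_model, "dynamic", top_k),
    }
    bands = rank_bands(dynamic_model, grid, top_k)
    baseline = classifier.feature_means_
    shapley = [
        group_shapley(classifier, bundle, baseline)
        for bundle in classifier.feature_bundles(records)
    ]
    return {
        "region_rankings": {
            branch: {
                "importance": rr.importance.tolist(),
                "top_indices": list(rr.top_indices),
                "labels": list(rr.labels),
            }
            for branch, rr in regions.items()
        },
        "band_ranking": {
            "importance": bands.importance.tolist(),
            "top_indices": list(bands.top_indices),
            "top_band_edges_hz": [list(bands.band_edges[i]) for i in bands.top_indices],
        },
        "shapley": [
            {
                "subject_id": gs.subject_id,
                "phi": gs.phi,
                "phi_abs": gs.phi_abs,
                "f_x": gs.f_x,
                "f_baseline": gs.f_baseline,
                "baseline": gs.baseline,
            }
            for gs in shapley
        ],
    }
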