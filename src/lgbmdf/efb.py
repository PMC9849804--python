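"""Exclusive feature bundling (EFB).

In sparse feature spaces many features are (nearly) mutually exclusive —
they are rarely nonzero on the same instance — so they can be merged into a
single encoded column, shrinking histogram construction from
``O(n_samples * n_features)`` to ``O(n_samples * n_bundles)``.

Bundling is greedy: features are visited in descending nonzero count and
placed into the first bundle whose accumulated conflicts (instances where
more than one member is nonzero) stay within ``max_conflict_rate * n``;
otherwise a new bundle is opened. Member values are shifted into disjoint
positive ranges by per-member offsets (the cumulative maximum value of
prior members), so a conflict-free bundle decodes uniquely back to
(member, raw value). Zero stays zero. Features containing negative values
are kept as untransformed singleton bundles, since the interval encoding
requires non-negative values.

The decode is exact whenever the offset additions are exact in floating
point (always so for the integer-valued sparse features the encoding is
meant for).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureBundle", "efb_bundle", "efb_transform", "efb_decode"]


@dataclass
class FeatureBundle:
    """One bundle of mutually (near-)exclusive features.

    ``offsets[m]`` is added to nonzero values of ``member_features[m]``;
    ``value_max[m]`` is that member's maximum raw value, fixing the width of
    its encoded interval ``(offset, offset + value_max]``.
    """

    member_features: list[int]
    offsets: list[float]
    value_max: list[float]
    conflict_count: int = 0


def _nonzero_mask(X: np.ndarray) -> np.ndarray:
    return X != 0.0


def efb_bundle(X: np.ndarray, max_conflict_rate: float) -> tuple[list[FeatureBundle], np.ndarray]:
    """Greedily bundle features and return (bundles, transformed matrix)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-d matrix")
    if not (0.0 <= max_conflict_rate < 1.0):
        raise ValueError("max_conflict_rate must lie in [0, 1)")
    n, s = X.shape
    nz = _nonzero_mask(X)
    nnz = nz.sum(axis=0)
    has_negative = (X < 0).any(axis=0)
    order = np.argsort(-nnz, kind="stable")  # ties toward lower feature id
    budget = max_conflict_rate * n

    bundles: list[FeatureBundle] = []
    used_masks: list[np.ndarray] = []  # union of member nonzero rows per bundle
    for f in order:
        f = int(f)
        placed = False
        if not has_negative[f]:
            for bi, bundle in enumerate(bundles):
                if len(bundle.member_features) == 1 and has_negative[bundle.member_features[0]]:
                    continue
                new_conflicts = int(np.count_nonzero(used_masks[bi] & nz[:, f]))
                if bundle.conflict_count + new_conflicts <= budget:
                    offset = bundle.offsets[-1] + bundle.value_max[-1]
                    bundle.member_features.append(f)
                    bundle.offsets.append(offset)
                    bundle.value_max.append(float(X[:, f].max(initial=0.0)))
                    bundle.conflict_count += new_conflicts
                    used_masks[bi] = used_masks[bi] | nz[:, f]
                    placed = True
                    break
        if not placed:
            bundles.append(
                FeatureBundle(
                    member_features=[f],
                    offsets=[0.0],
                    value_max=[float(np.abs(X[:, f]).max(initial=0.0))],
                )
            )
            used_masks.append(nz[:, f].copy())
    return bundles, efb_transform(X, bundles)


def efb_transform(X: np.ndarray, bundles: list[FeatureBundle]) -> np.ndarray:
    """Encode a raw matrix into one column per bundle.

    Within a bundle, members are applied in order, so on a conflicting row
    the last-listed nonzero member wins (conflicts only arise when
    ``max_conflict_rate > 0``).
    """
    X = np.asarray(X, dtype=np.float64)
    out = np.zeros((X.shape[0], len(bundles)), dtype=np.float64)
    for bi, bundle in enumerate(bundles):
        col = out[:, bi]
        for f, offset in zip(bundle.member_features, bundle.offsets):
            v = X[:, f]
            m = v != 0.0
            col[m] = v[m] + offset
    return out


def efb_decode(Xt: np.ndarray, bundles: list[FeatureBundle], n_features: int) -> np.ndarray:
    """Invert :func:`efb_transform` (exact for conflict-free bundles)."""
    Xt = np.asarray(Xt, dtype=np.float64)
    if Xt.shape[1] != len(bundles):
        raise ValueError("column count does not match the bundle list")
    out = np.zeros((Xt.shape[0], n_features), dtype=np.float64)
    for bi, bundle in enumerate(bundles):
        col = Xt[:, bi]
        if len(bundle.member_features) == 1:
            out[:, bundle.member_features[0]] = col
            continue
        for f, offset, vmax in zip(bundle.member_features, bundle.offsets, bundle.value_max):
            m = (col > offset) & (col <= offset + vmax)
            out[m, f] = col[m] - offset
    return out
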