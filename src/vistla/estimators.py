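"""Plug-in information estimators and the Kendall transformation.

All quantities are reported in **nats** (natural logarithm).  The estimators
are plain maximum-likelihood (plug-in) estimates on contingency tables: no
small-sample bias correction is applied.  Two routes turn raw features into
the categorical codes the plug-in formulas need:

* **MLE route** — categorical and binary features are used as-is; ordinal
  (continuous) features are first discretized into equal-frequency bins
  (:func:`discretize`).
* **KT route** — ordinal and binary features are expanded by the Kendall
  transformation (:func:`kendall_transform`) into ``n(n-1)`` pairwise order
  tokens (UP / DOWN / TIE), after which the same plug-in formulas apply.
  The transform is invariant under strictly monotone maps of the input, which
  makes the resulting estimates rank-based.  Unordered features with more
  than two categories cannot be ranked; split them first
  (:func:`split_categorical`).

The module also provides :class:`Estimator`, a table-level cache of encoded
columns and pairwise/conditional mutual informations used by the path search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataTable, Feature

#: Token codes emitted by the Kendall transformation.
KT_DOWN, KT_TIE, KT_UP = 0, 1, 2


# --------------------------------------------------------------------------
# low-level plug-in machinery
# --------------------------------------------------------------------------

def _as_codes(x) -> np.ndarray:
    """Integer codes for a Feature or a raw vector."""
    if isinstance(x, Feature):
        return x.codes()
    x = np.asarray(x)
    _, inv = np.unique(x, return_inverse=True)
    return inv.astype(np.int64)


def _entropy_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    p = counts / codes.size
    return float(-(p * np.log(p)).sum())


def _joint(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Codes of the paired variable (a,b)."""
    kb = int(cb.max()) + 1
    return ca * kb + cb


def entropy(x) -> float:
    """Plug-in (MLE) entropy of a discrete feature, in nats.

    ``H(X) = -Σ_k p̂_k ln p̂_k`` over observed category frequencies.
    Bounded by ``ln`` of the number of distinct observed values.
    """
    codes = _as_codes(x)
    if codes.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    return _entropy_codes(codes)


def mutual_info(x, y) -> float:
    """Plug-in mutual information ``I(X;Y) = H(X) + H(Y) - H(X,Y)`` in nats.

    Symmetric and non-negative (tiny negative rounding residues are clamped
    to zero).  Inputs must be categorical-coded: discretize or
    Kendall-transform ordinal features first.
    """
    cx, cy = _as_codes(x), _as_codes(y)
    if cx.size != cy.size:
        raise ValueError(f"length mismatch: {cx.size} vs {cy.size}")
    mi = _entropy_codes(cx) + _entropy_codes(cy) - _entropy_codes(_joint(cx, cy))
    return max(mi, 0.0)


def cond_mutual_info(x, y, z) -> float:
    """Plug-in conditional mutual information ``I(X;Y|Z)`` in nats.

    Computed as ``H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)``; non-negative.
    """
    cx, cy, cz = _as_codes(x), _as_codes(y), _as_codes(z)
    if not (cx.size == cy.size == cz.size):
        raise ValueError("length mismatch among x, y, z")
    cxz = _joint(cx, cz)
    cyz = _joint(cy, cz)
    cxyz = _joint(cxz, cy)
    cmi = (
        _entropy_codes(cxz)
        + _entropy_codes(cyz)
        - _entropy_codes(cxyz)
        - _entropy_codes(cz)
    )
    return max(cmi, 0.0)


@dataclass(frozen=True)
class TripleInfo:
    """The three information quantities of an ordered feature triple.

    ``ii_abc = i_ab - i_ab_given_c`` is the interaction information
    ``I(A;B;C)``: positive for redundancy (chain/fork structure), negative
    for synergy (e.g. an XOR collider).  Its value is invariant under any
    permutation of the three arguments.
    """

    i_ab: float
    i_ab_given_c: float

    @property
    def ii_abc(self) -> float:
        return self.i_ab - self.i_ab_given_c


def interaction_info(a, b, c) -> TripleInfo:
    """Interaction information ``I(A;B;C) = I(A;B) - I(A;B|C)`` in nats."""
    return TripleInfo(mutual_info(a, b), cond_mutual_info(a, b, c))


# --------------------------------------------------------------------------
# feature transforms
# --------------------------------------------------------------------------

def kendall_transform(x: Feature) -> Feature:
    """Expand an ordinal or binary feature into pairwise order tokens.

    For every ordered observation pair ``(i, j)``, ``i != j``, emits UP if
    ``x_j > x_i``, DOWN if ``x_j < x_i``, TIE if equal.  Pairs are enumerated
    lexicographically over ``(i, j)`` — the same fixed order for every
    feature of a table — so transformed columns stay row-aligned and joint
    contingency tables over them are meaningful.  Output length is
    ``n(n-1)``; token codes are ``KT_DOWN``/``KT_TIE``/``KT_UP`` = 0/1/2.
    """
    if x.kind == "categorical" and len(x.categories()) > 2:
        raise ValueError(
            f"feature {x.name!r} is unordered with >2 categories and cannot "
            "be Kendall-transformed; split it into per-category indicators "
            "with split_categorical() first"
        )
    n = x.n
    if n < 2:
        raise ValueError("Kendall transformation needs at least 2 observations")
    v = x.codes() if x.kind != "ordinal" else np.asarray(x.values, dtype=float)
    diff = np.sign(v[None, :] - v[:, None])  # diff[i, j] = sign(x_j - x_i)
    off_diag = ~np.eye(n, dtype=bool)
    tokens = (diff[off_diag] + 1).astype(np.int8)  # row-major = lexicographic
    return Feature(x.name, "categorical", tokens)


def discretize(x: Feature, bins: int = 10) -> Feature:
    """Equal-frequency binning of an ordinal feature into ≤ ``bins`` categories.

    Observations sharing a value always share a bin (ties are kept together),
    so the number of categories never exceeds the number of distinct values.
    """
    if bins < 2:
        raise ValueError("bins must be at least 2")
    if x.kind == "categorical":
        raise ValueError(f"feature {x.name!r} is categorical; nothing to discretize")
    v = np.asarray(x.values, dtype=float)
    uniq = np.unique(v)
    if len(uniq) <= bins:
        codes = np.searchsorted(uniq, v)
    else:
        # quantile edges; duplicate edges collapse so categories may be < bins
        qs = np.quantile(v, np.linspace(0, 1, bins + 1))
        edges = np.unique(qs[1:-1])
        codes = np.searchsorted(edges, v, side="right")
    return Feature(x.name, "categorical", codes.astype(np.int64))


def split_categorical(x: Feature) -> list[Feature]:
    """One-hot split of a k>2-category feature into k binary indicators.

    Indicator features are named ``name=category`` and jointly determine the
    original feature (each observation is 1 in exactly one indicator).
    """
    cats = x.categories()
    if len(cats) <= 2:
        raise ValueError(
            f"feature {x.name!r} has {len(cats)} categories; splitting is "
            "only defined for more than two"
        )
    return [
        Feature(f"{x.name}={cat}", "binary", (x.values == cat).astype(np.int64))
        for cat in cats
    ]


def estimate_mi(x: Feature, y: Feature, method: str = "mle", bins: int = 10) -> float:
    """Mutual information between two features under a named estimator route.

    ``method="mle"`` discretizes ordinal inputs then applies the plug-in
    formula; ``method="kt"`` Kendall-transforms both inputs (shared pair
    enumeration) first.
    """
    if method == "mle":
        def prep(f: Feature) -> Feature:
            return discretize(f, bins) if f.kind == "ordinal" else f
    elif method == "kt":
        prep = kendall_transform
    else:
        raise ValueError(f"unknown estimator method {method!r}; use 'mle' or 'kt'")
    return mutual_info(prep(x), prep(y))


# --------------------------------------------------------------------------
# table-level cached estimator
# --------------------------------------------------------------------------

class Estimator:
    """Caches encoded columns and information quantities for one table.

    Encodes every column once according to the chosen route, then serves
    pairwise MI ``mi(i, j)`` and conditional MI ``cmi(i, j, k)`` from caches.
    The path search evaluates O(m²) initial triples plus one triple per edge
    relaxation; caching makes repeated gate evaluations cheap.
    """

    #: estimator routes understood by the constructor
    METHODS = ("mle", "kt")

    def __init__(self, table: DataTable, method: str = "mle", bins: int = 10):
        if method not in self.METHODS:
            raise ValueError(f"unknown estimator method {method!r}")
        self.table = table
        self.method = method
        self.bins = bins
        self.codes: list[np.ndarray] = []
        for f in table.features:
            if method == "mle":
                enc = discretize(f, bins) if f.kind == "ordinal" else f
                self.codes.append(enc.codes())
            else:
                self.codes.append(kendall_transform(f).values.astype(np.int64))
        self._h: dict[tuple[int, ...], float] = {}
        self._mi: dict[tuple[int, int], float] = {}
        self._cmi: dict[tuple[int, int, int], float] = {}

    def _entropy(self, key: tuple[int, ...]) -> float:
        h = self._h.get(key)
        if h is None:
            codes = self.codes[key[0]]
            for i in key[1:]:
                codes = _joint(codes, self.codes[i])
            h = _entropy_codes(codes)
            self._h[key] = h
        return h

    def mi(self, i: int, j: int) -> float:
        """Cached plug-in I(X_i; X_j) in nats."""
        key = (i, j) if i <= j else (j, i)
        v = self._mi.get(key)
        if v is None:
            v = max(
                self._entropy((key[0],))
                + self._entropy((key[1],))
                - self._entropy(key),
                0.0,
            )
            self._mi[key] = v
        return v

    def cmi(self, i: int, j: int, k: int) -> float:
        """Cached plug-in I(X_i; X_j | X_k) in nats."""
        a, b = (i, j) if i <= j else (j, i)
        v = self._cmi.get((a, b, k))
        if v is None:
            v = max(
                self._entropy(tuple(sorted((a, k))))
                + self._entropy(tuple(sorted((b, k))))
                - self._entropy(tuple(sorted((a, b, k))))
                - self._entropy((k,)),
                0.0,
            )
            self._cmi[(a, b, k)] = v
        return v
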