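"""Tabular container for anchored information systems.

A :class:`DataTable` holds ``n`` observations of ``m`` features, one of which
is designated the *anchor* ``Y`` — the perturbation or intervention whose
influence is traced through the remaining features.  Each feature carries a
*kind* that decides how information quantities are estimated from it:

``categorical``
    unordered discrete codes (strings or integers);
``binary``
    discrete with at most two distinct codes (ordered by code when a
    rank-based estimator needs an order);
``ordinal``
    real- or integer-valued with a meaningful order (continuous measurements
    belong here and are discretized or Kendall-transformed downstream).

Missing values are rejected on construction: imputation is a pre-processing
concern outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("categorical", "binary", "ordinal")


@dataclass
class Feature:
    """A single named column with its measurement kind.

    Parameters
    ----------
    name : str
        Column identifier, unique within a table.
    kind : {"categorical", "binary", "ordinal"}
        How the values are to be interpreted by estimators.
    values : ndarray
        Length-``n`` vector; category codes for categorical/binary, numbers
        for ordinal.  Must not contain missing values.
    """

    name: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(
                f"feature {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {KINDS}"
            )
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError(f"feature {self.name!r}: values must be 1-D")
        if self.values.size == 0:
            raise ValueError(f"feature {self.name!r}: empty value vector")
        if pd.isna(self.values).any():
            raise ValueError(
                f"feature {self.name!r} contains missing values; impute or "
                "drop them before building a table"
            )
        if self.kind == "binary" and len(self.categories()) > 2:
            raise ValueError(
                f"feature {self.name!r} declared binary but has "
                f"{len(self.categories())} distinct codes"
            )
        if self.kind == "ordinal" and not np.issubdtype(
            self.values.dtype, np.number
        ):
            raise ValueError(
                f"feature {self.name!r} declared ordinal but is not numeric"
            )

    @property
    def n(self) -> int:
        return self.values.size

    def categories(self) -> np.ndarray:
        """Distinct values in sorted order (the code book)."""
        return np.unique(self.values)

    def codes(self) -> np.ndarray:
        """Integer codes 0..k-1 assigned by sorted distinct value.

        The assignment is deterministic and, for ordinal/binary features,
        monotone in the underlying value, so rank-based transforms can use
        the codes directly.
        """
        _, inv = np.unique(self.values, return_inverse=True)
        return inv.astype(np.int64)


def infer_kind(values: np.ndarray) -> str:
    """Kind inference rule: ≤2 distinct codes → binary; numeric → ordinal;
    otherwise categorical."""
    values = np.asarray(values)
    distinct = pd.unique(values[~pd.isna(values)])
    if len(distinct) <= 2:
        return "binary"
    if np.issubdtype(values.dtype, np.number):
        return "ordinal"
    return "categorical"


class DataTable:
    """An n×m observation matrix with per-feature kinds and a designated anchor.

    Build one from a :class:`pandas.DataFrame` with :meth:`from_dataframe`,
    from a delimited text file via :func:`vistla.io.read_table`, or directly
    from a list of :class:`Feature` objects.
    """

    def __init__(self, features: list[Feature], anchor: str):
        if not features:
            raise ValueError("a table needs at least one feature")
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in table")
        lengths = {f.n for f in features}
        if len(lengths) != 1:
            raise ValueError(f"features have differing lengths: {sorted(lengths)}")
        if anchor not in names:
            raise ValueError(
                f"anchor {anchor!r} not among features {names}"
            )
        self.features = list(features)
        self.anchor = anchor
        self._index = {f.name: i for i, f in enumerate(self.features)}

    # ------------------------------------------------------------------ views
    @property
    def n(self) -> int:
        """Number of observations."""
        return self.features[0].n

    @property
    def m(self) -> int:
        """Number of features, anchor included."""
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def anchor_index(self) -> int:
        return self._index[self.anchor]

    @property
    def non_anchor_indices(self) -> list[int]:
        return [i for i in range(self.m) if i != self.anchor_index]

    def index(self, name: str) -> int:
        return self._index[name]

    def feature(self, key: int | str) -> Feature:
        if isinstance(key, str):
            key = self._index[key]
        return self.features[key]

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        anchor: str,
        kinds: dict[str, str] | None = None,
    ) -> "DataTable":
        """Build a table from a DataFrame, inferring kinds where not hinted.

        Raises a single error naming every column with missing values.
        """
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty table")
        bad = [c for c in df.columns if df[c].isna().any()]
        if bad:
            raise ValueError(
                f"missing values in column(s) {bad}; impute or drop them first"
            )
        kinds = dict(kinds or {})
        feats = []
        for col in df.columns:
            vals = df[col].to_numpy()
            kind = kinds.get(col) or infer_kind(vals)
            feats.append(Feature(str(col), kind, vals))
        return cls(feats, anchor)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f.name: f.values for f in self.features},
            columns=self.names,
        )

    # ------------------------------------------------------------- transforms
    def split_categoricals(self) -> "DataTable":
        """Replace every non-anchor categorical feature with >2 categories by
        per-category binary indicators named ``feature=category``.

        Needed before rank-based (Kendall) estimation, which cannot order
        multi-category codes.
        """
        from .estimators import split_categorical

        out: list[Feature] = []
        for f in self.features:
            if (
                f.name != self.anchor
                and f.kind == "categorical"
                and len(f.categories()) > 2
            ):
                out.extend(split_categorical(f))
            else:
                out.append(f)
        return DataTable(out, self.anchor)

    def permuted(self, seed) -> "DataTable":
        """Independently shuffle every feature (anchor included).

        Marginals are preserved exactly; all inter-feature relationships are
        destroyed.  ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
        """
        rng = np.random.default_rng(seed)
        feats = [
            Feature(f.name, f.kind, rng.permutation(f.values))
            for f in self.features
        ]
        return DataTable(feats, self.anchor)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DataTable(n={self.n}, m={self.m}, anchor={self.anchor!r}, "
            f"features={self.names})"
        )
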