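"""Deficit-accumulation frailty index (FI) construction.

The FI of Mitnitski and Rockwood operationalizes frailty as the proportion of
health deficits an individual accumulates out of a fixed battery of items
(typically 30-60, here defaulting to 40). Each raw item is recoded to a
deficit score in [0, 1] by a declarative coding rule; the FI for a record is
the sum of its non-missing deficit scores divided by the number of non-missing
items, and is reported only when at least ``min_valid`` items (default 35 of
40) carry valid information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, SchemaError

__all__ = [
    "ItemSpec",
    "load_item_specs",
    "apply_item_spec",
    "compute_fi",
    "FrailtyIndex",
    "bundled_item_specs",
]


@dataclass
class ItemSpec:
    """Coding rule mapping one raw item to a deficit score.

    kind="threshold": numeric rule — deficit (score 1) when the value is on
    the deficit side of ``cutoff`` (``direction`` "ge" or "le"), else 0.
    kind="categorical": ``mapping`` from raw category to a score in [0, 1];
    categories absent from the mapping become missing (counted as warnings).
    kind="identity": the raw value is already a score in [0, 1]; out-of-range
    values become missing.
    """

    item_id: str
    kind: str = "threshold"
    description: str = ""
    cutoff: float | None = None
    direction: str = "ge"
    mapping: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("threshold", "categorical", "identity"):
            raise ConfigurationError(
                f"item {self.item_id}: kind must be threshold/categorical/"
                f"identity, got {self.kind!r}"
            )
        if self.kind == "threshold":
            if self.cutoff is None:
                raise ConfigurationError(
                    f"item {self.item_id}: threshold rule needs a cutoff"
                )
            if self.direction not in ("ge", "le"):
                raise ConfigurationError(
                    f"item {self.item_id}: direction must be 'ge' or 'le'"
                )
        if self.kind == "categorical":
            bad = {
                k: v
                for k, v in self.mapping.items()
                if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0)
            }
            if bad:
                raise ConfigurationError(
                    f"item {self.item_id}: mapped scores outside [0, 1]: {bad}"
                )

    def score(self, values: pd.Series) -> tuple[pd.Series, int]:
        """Apply the rule; return (scores with NaN for missing, warning count).

        Warnings count raw values that were present but could not be mapped
        (unknown category, non-numeric value, out-of-range identity score).
        """
        if self.kind == "threshold":
            numeric = pd.to_numeric(values, errors="coerce")
            warnings = int((numeric.isna() & values.notna()).sum())
            if self.direction == "ge":
                scores = (numeric >= self.cutoff).astype(float)
            else:
                scores = (numeric <= self.cutoff).astype(float)
            scores[numeric.isna()] = np.nan
            return scores, warnings
        if self.kind == "categorical":
            scores = values.map(self.mapping).astype(float)
            warnings = int((scores.isna() & values.notna()).sum())
            return scores, warnings
        numeric = pd.to_numeric(values, errors="coerce")
        out_of_range = (numeric < 0) | (numeric > 1)
        warnings = int(
            ((numeric.isna() & values.notna()) | out_of_range).sum()
        )
        scores = numeric.where(~out_of_range)
        return scores.astype(float), warnings


def load_item_specs(path) -> list[ItemSpec]:
    """Read a list of item coding rules from a YAML file.

    The file holds a list of mappings with keys matching :class:`ItemSpec`
    fields (``item_id`` required; ``kind`` defaults to threshold).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError("item spec file must hold a list of items")
    return [ItemSpec(**entry) for entry in raw]


def bundled_item_specs() -> list[ItemSpec]:
    """The bundled synthetic 40-item battery (ships with the package).

    A stand-in battery spanning the usual FI dimensions (self-rated health,
    morbidities, ADL/IADL difficulties, mobility, sensory items, BMI, grip);
    its cutoffs are synthetic, not any survey's restricted coding.
    """
    from importlib.resources import files

    path = files("mortalq.data") / "synthetic_items_40.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return [ItemSpec(**entry) for entry in raw]


def apply_item_spec(
    raw_panel: pd.DataFrame, specs: list[ItemSpec]
) -> pd.DataFrame:
    """Recode a raw item panel into a deficit panel.

    ``raw_panel`` must contain one column per ``spec.item_id`` (plus any
    identifier columns, which are carried through). Returns a DataFrame with
    the identifier columns and one deficit-score column per item; the total
    number of unmappable raw values is reported in
    ``result.attrs["n_warnings"]``.
    """
    missing_cols = [s.item_id for s in specs if s.item_id not in raw_panel.columns]
    if missing_cols:
        raise SchemaError(
            f"raw panel lacks columns for items: {missing_cols}"
        )
    item_ids = [s.item_id for s in specs]
    id_cols = [c for c in raw_panel.columns if c not in item_ids]
    out = raw_panel[id_cols].copy()
    n_warnings = 0
    for spec in specs:
        scores, warn = spec.score(raw_panel[spec.item_id])
        out[spec.item_id] = scores
        n_warnings += warn
    out.attrs["n_warnings"] = n_warnings
    return out


def compute_fi(
    deficits: pd.DataFrame,
    min_valid: int = 35,
    n_items: int = 40,
    item_columns: list[str] | None = None,
) -> pd.Series:
    """Compute the FI per row of a deficit panel.

    FI = (sum of non-missing deficit scores) / (number of non-missing items),
    reported only for rows with at least ``min_valid`` non-missing items out
    of the ``n_items`` battery; otherwise NaN. The denominator counts the
    items actually considered, so a missing item never changes the FI, only
    the validity count.
    """
    if min_valid > n_items:
        raise ConfigurationError(
            f"min_valid ({min_valid}) exceeds n_items ({n_items})"
        )
    if item_columns is None:
        item_columns = [
            c for c in deficits.columns if pd.api.types.is_float_dtype(deficits[c])
        ]
    if len(item_columns) != n_items:
        raise ConfigurationError(
            f"expected {n_items} item columns, found {len(item_columns)}"
        )
    scores = deficits[item_columns]
    if ((scores < 0) | (scores > 1)).any().any():
        raise ConfigurationError("deficit scores must lie in [0, 1]")
    n_valid = scores.notna().sum(axis=1)
    fi = scores.sum(axis=1, min_count=1) / n_valid
    fi[n_valid < min_valid] = np.nan
    return fi.rename("fi")


class FrailtyIndex(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer computing the FI from deficit scores.

    Parameters
    ----------
    min_valid : int, default 35
        Minimum number of non-missing items for a valid FI.
    n_items : int, default 40
        Size of the item battery (validated against the input).
    """

    def __init__(self, min_valid: int = 35, n_items: int = 40):
        self.min_valid = min_valid
        self.n_items = n_items

    def fit(self, X: pd.DataFrame, y=None):
        if self.min_valid > self.n_items:
            raise ConfigurationError(
                f"min_valid ({self.min_valid}) exceeds n_items ({self.n_items})"
            )
        self.item_columns_ = [
            c for c in X.columns if pd.api.types.is_float_dtype(X[c])
        ]
        self.n_features_in_ = len(self.item_columns_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "item_columns_"):
            self.fit(X)
        return compute_fi(
            X,
            min_valid=self.min_valid,
            n_items=self.n_items,
            item_columns=self.item_columns_,
        )
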