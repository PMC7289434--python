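"""Feature-set algebra and cross-facility / cross-model transfer evaluation.

A feature set selected at one facility is *transferred* to another by
fitting a model with that set on the target facility's data and comparing
its test error with the error of the facility's own optimal set. The
transfer ratio is the mean over replicate splits of
``MAE(transferred) / MAE(optimal)``: 1.00 means the transferred set is as
good as the local optimum, 1.06 means 6% worse; with a forest model the
2.5/97.5 percentile interval of the per-split ratios is reported as a 95%
confidence interval. Ratios below 1 can occur when the transferred set is
larger than the local optimum.

Walk-in applicability filtering supports two policies (see the catalog
module): ``strict`` drops every feature that needs a real appointment
schedule; ``proxy`` keeps features computable under the
arrival-as-scheduled proxy and drops only the delay-defined counters.

The package ships the reduced feature sets published for four outpatient
imaging facilities (stepwise-LR and random-forest selections for three
scheduled facilities, as unions, and for one walk-in facility) as reviewable
CSV fixtures; see :func:`reference_feature_set`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, build_catalog
from .errors import ConfigError, EmptyInputError
from .events import FacilityType
from .stepwise import SplitSpec, evaluate_feature_set, split_frames

__all__ = [
    "FeatureSet",
    "TransferRatio",
    "union_sets",
    "intersect_sets",
    "applicable_subset",
    "transfer_ratio",
    "transfer_matrix",
    "cross_model_transfer",
    "reference_feature_set",
    "REFERENCE_SETS",
]


@dataclass(frozen=True)
class FeatureSet:
    """A named, ordered list of distinct feature names."""

    source: str
    features: tuple[str, ...]

    def __init__(self, source: str, features: Sequence[str]):
        ordered = list(dict.fromkeys(features))
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "features", tuple(ordered))

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def unresolved(self, catalog: FeatureCatalog) -> list[str]:
        """Names not present in the catalog (reported, never silently dropped)."""
        return [f for f in self.features if f not in catalog]


def union_sets(sets: Sequence[FeatureSet], source: str = "union") -> FeatureSet:
    """Distinct names across the sets, ordered by first appearance."""
    if not sets:
        raise EmptyInputError("no feature sets given")
    names: list[str] = []
    for fs in sets:
        names.extend(fs.features)
    return FeatureSet(source, names)


def intersect_sets(
    a: FeatureSet, b: FeatureSet, catalog: Optional[FeatureCatalog] = None
) -> FeatureSet:
    """Names present in both sets, in catalog order (unknown names last, in
    ``a``'s order)."""
    common = [f for f in a.features if f in set(b.features)]
    if catalog is not None:
        known = sorted(
            [f for f in common if f in catalog], key=catalog.order_index
        )
        common = known + [f for f in common if f not in catalog]
    return FeatureSet(f"{a.source}&{b.source}", common)


def applicable_subset(
    fs: FeatureSet,
    facility_type: Union[str, FacilityType],
    catalog: Optional[FeatureCatalog] = None,
    policy: str = "proxy",
) -> FeatureSet:
    """Restrict a feature set to what the facility type supports.

    Scheduled and hybrid facilities keep everything. For walk-in facilities
    ``policy='strict'`` keeps only features flagged ``walkin_applicable``
    (no schedule-dependent features at all) while ``policy='proxy'`` keeps
    features flagged ``walkin_proxy_applicable`` (arrival time stands in
    for the scheduled time; only delay-defined counters are dropped).
    Names missing from the catalog are kept, so that external selections
    with idiosyncratic spellings survive filtering; they are discoverable
    via :meth:`FeatureSet.unresolved`.
    """
    facility_type = FacilityType.coerce(facility_type)
    if facility_type is not FacilityType.WALKIN:
        return fs
    catalog = catalog or build_catalog(facility_type)
    if policy not in ("strict", "proxy"):
        raise ConfigError(f"unknown applicability policy {policy!r}")
    kept = []
    for name in fs.features:
        if name not in catalog:
            kept.append(name)
            continue
        d = catalog[name]
        ok = d.walkin_applicable if policy == "strict" else d.walkin_proxy_applicable
        if ok:
            kept.append(name)
    return FeatureSet(f"{fs.source}|walkin-{policy}", kept)


@dataclass
class TransferRatio:
    """Mean error ratio of a transferred set vs the local optimum."""

    ratio: float
    ci_low: float
    ci_high: float
    per_split: list[float] = field(default_factory=list)
    n_replicates: int = 0


def transfer_ratio(
    matrix: pd.DataFrame,
    transferred: FeatureSet,
    optimal: FeatureSet,
    model: str = "linear",
    splits: Sequence[SplitSpec] = (),
    seed: int = 0,
    rf_params=None,
) -> TransferRatio:
    """Per split, fit both feature sets on the training window and form
    ``MAE(transferred) / MAE(optimal)`` on the test window; return the mean
    ratio and the 2.5/97.5 percentile interval across splits."""
    if len(transferred) == 0 or len(optimal) == 0:
        raise ConfigError("feature sets must be non-empty after applicability filtering")
    if not splits:
        raise EmptyInputError("no train/test splits given")
    ratios = []
    for spec in splits:
        train, test = split_frames(matrix, spec)
        mae_t = evaluate_feature_set(
            list(transferred), train, test, model=model, seed=seed, rf_params=rf_params
        )
        mae_o = evaluate_feature_set(
            list(optimal), train, test, model=model, seed=seed, rf_params=rf_params
        )
        ratios.append(mae_t / mae_o)
    arr = np.asarray(ratios)
    return TransferRatio(
        ratio=float(arr.mean()),
        ci_low=float(np.percentile(arr, 2.5)),
        ci_high=float(np.percentile(arr, 97.5)),
        per_split=ratios,
        n_replicates=len(ratios),
    )


def transfer_matrix(
    matrices: dict[str, pd.DataFrame],
    facility_types: dict[str, Union[str, FacilityType]],
    optimal_sets: dict[str, FeatureSet],
    extra_sets: Sequence[FeatureSet] = (),
    model: str = "linear",
    splits: Optional[dict[str, Sequence[SplitSpec]]] = None,
    catalog: Optional[FeatureCatalog] = None,
    policy: str = "proxy",
    seed: int = 0,
    rf_params=None,
) -> pd.DataFrame:
    """Ratio matrix: rows = data facilities, columns = feature-set sources
    (each facility's optimal set plus any extra sets such as their union).
    Diagonal cells are 1 by definition. Sets are applicability-filtered per
    data facility before fitting."""
    catalog = catalog or build_catalog()
    sources = {fac: fs for fac, fs in optimal_sets.items()}
    for fs in extra_sets:
        sources[fs.source] = fs
    out = pd.DataFrame(index=list(matrices), columns=list(sources), dtype=float)
    for fac, matrix in matrices.items():
        own = optimal_sets[fac]
        for label, fs in sources.items():
            usable = applicable_subset(fs, facility_types[fac], catalog, policy)
            result = transfer_ratio(
                matrix,
                usable,
                own,
                model=model,
                splits=splits[fac],
                seed=seed,
                rf_params=rf_params,
            )
            out.loc[fac, label] = result.ratio
    return out


def cross_model_transfer(
    matrix: pd.DataFrame,
    lr_set: FeatureSet,
    rf_set: FeatureSet,
    splits: Sequence[SplitSpec],
    seed: int = 0,
    rf_params=None,
) -> pd.DataFrame:
    """2×2 table of mean test MAE (minutes): each model (rows ``linear``,
    ``forest``) fitted with each selection's feature set (columns)."""
    out = pd.DataFrame(
        index=["linear", "forest"],
        columns=[lr_set.source, rf_set.source],
        dtype=float,
    )
    for model in ("linear", "forest"):
        for fs in (lr_set, rf_set):
            maes = []
            for spec in splits:
                train, test = split_frames(matrix, spec)
                maes.append(
                    evaluate_feature_set(
                        list(fs), train, test, model=model, seed=seed, rf_params=rf_params
                    )
                )
            out.loc[model, fs.source] = float(np.mean(maes))
    return out


# Published reduced selections from a multi-site outpatient imaging study,
# shipped as reviewable CSV fixtures. Keys: selection model + facility kind.
REFERENCE_SETS = (
    "lr_union_scheduled",  # stepwise-LR union over three scheduled facilities
    "lr_top10_walkin",  # stepwise-LR top 10 for the walk-in facility
    "rf_union_scheduled",  # random-forest union over three scheduled facilities
    "rf_top10_walkin",  # random-forest top 10 for the walk-in facility
)


def reference_feature_set(name: str) -> FeatureSet:
    if name not in REFERENCE_SETS:
        raise KeyError(f"unknown reference set {name!r}; choose from {REFERENCE_SETS}")
    path = resources.files("queueflow.data").joinpath(f"{name}.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    return FeatureSet(name, list(df["feature"]))
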