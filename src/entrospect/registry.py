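"""Catalog of pipeline components and the combinatorial route count.

Every component carries metadata (count-based flag, measure compatibility)
so that compatibility between components is decided by metadata alone —
never by special-cased pairs.  ``enumerate_routes`` derives the number of
computable measures from the catalogs at call time; nothing is hard-coded.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import complexity_estimators as _cx
from . import differential as _diff
from . import discrete as _disc
from . import measures as _ms
from . import outcome_spaces as _os
from . import probabilities as _pb

__all__ = [
    "OUTCOME_SPACES",
    "PROBABILITIES_ESTIMATORS",
    "INFORMATION_MEASURES",
    "DISCRETE_ESTIMATORS",
    "DIFFERENTIAL_ESTIMATORS",
    "COMPLEXITY_ESTIMATORS",
    "ALIASES",
    "enumerate_routes",
    "resolve_outcome_space",
    "resolve_measure",
    "resolve_discrete_estimator",
    "resolve_probabilities_estimator",
    "resolve_complexity_estimator",
]


@dataclass(frozen=True)
class SpaceEntry:
    factory: type
    count_based: bool
    spatial: bool = False


# name -> component entry; 9 count-based + 3 weight-based spaces
OUTCOME_SPACES: dict[str, SpaceEntry] = {
    "unique_elements": SpaceEntry(_os.UniqueElements, True),
    "value_binning": SpaceEntry(_os.ValueBinning, True),
    "ordinal": SpaceEntry(_os.OrdinalPatterns, True),
    "weighted_ordinal": SpaceEntry(_os.WeightedOrdinalPatterns, False),
    "amplitude_ordinal": SpaceEntry(_os.AmplitudeAwareOrdinalPatterns, False),
    "dispersion": SpaceEntry(_os.Dispersion, True),
    "cosine_similarity": SpaceEntry(_os.CosineSimilarityBinning, True),
    "bubble_swaps": SpaceEntry(_os.BubbleSortSwaps, True),
    "pair_distances": SpaceEntry(_os.SequentialPairDistances, True),
    "power_spectrum": SpaceEntry(_os.PowerSpectrum, False),
    "spatial_ordinal": SpaceEntry(_os.SpatialOrdinalPatterns, True, spatial=True),
    "spatial_dispersion": SpaceEntry(_os.SpatialDispersion, True, spatial=True),
}

PROBABILITIES_ESTIMATORS: dict[str, type] = {
    "relative_amount": _pb.RelativeAmount,
    "add_constant": _pb.AddConstant,
    "bayesian": _pb.BayesianRegularization,
    "shrinkage": _pb.Shrinkage,
}

INFORMATION_MEASURES: dict[str, type] = {
    "shannon": _ms.Shannon,
    "renyi": _ms.Renyi,
    "tsallis": _ms.Tsallis,
    "curado": _ms.Curado,
    "kaniadakis": _ms.Kaniadakis,
    "stretched_exponential": _ms.StretchedExponential,
    "shannon_extropy": _ms.ShannonExtropy,
    "renyi_extropy": _ms.RenyiExtropy,
    "tsallis_extropy": _ms.TsallisExtropy,
    "fluctuation_complexity": _ms.FluctuationComplexity,
}

# name -> (class, applicability): 'generic' works for every measure,
# 'shannon' only for the Shannon definition
DISCRETE_ESTIMATORS: dict[str, tuple[type, str]] = {
    "plugin": (_disc.PlugIn, "generic"),
    "jackknife": (_disc.Jackknife, "generic"),
    "miller_madow": (_disc.MillerMadow, "shannon"),
    "horvitz_thompson": (_disc.HorvitzThompson, "shannon"),
    "chao_shen": (_disc.ChaoShen, "shannon"),
}

# name -> (class, supported measure definitions)
DIFFERENTIAL_ESTIMATORS: dict[str, tuple[type, tuple[str, ...]]] = {
    "vasicek": (_diff.Vasicek, ("shannon",)),
    "ebrahimi": (_diff.Ebrahimi, ("shannon",)),
    "correa": (_diff.Correa, ("shannon",)),
    "alizadeh_arghami": (_diff.AlizadehArghami, ("shannon",)),
    "kozachenko_leonenko": (_diff.KozachenkoLeonenko, ("shannon",)),
    "kraskov": (_diff.Kraskov, ("shannon",)),
    "leonenko_prozanto_savani": (
        _diff.LeonenkoProzantoSavani, ("shannon", "renyi", "tsallis")),
}

COMPLEXITY_ESTIMATORS: dict[str, type] = {
    "approximate_entropy": _cx.ApproximateEntropy,
    "sample_entropy": _cx.SampleEntropy,
    "lempel_ziv_76": _cx.LempelZiv76,
    "missing_dispersion_patterns": _cx.MissingDispersionPatterns,
    "reverse_dispersion": _cx.ReverseDispersion,
    "statistical_complexity": _cx.StatisticalComplexity,
    "bubble_entropy": _cx.BubbleEntropy,
}

# Convenience aliases resolving to explicit pipeline spellings.  These are
# not genuinely new entropies: e.g. "permutation entropy" is the Shannon
# entropy of the ordinal-pattern PMF.
ALIASES: dict[str, dict] = {
    "entropy_permutation": {"kind": "discrete", "ospace": "ordinal"},
    "entropy_dispersion": {"kind": "discrete", "ospace": "dispersion"},
    "entropy_spectral": {"kind": "discrete", "ospace": "power_spectrum"},
    "entropy_sample": {"kind": "complexity", "estimator": "sample_entropy"},
    "entropy_approximate": {"kind": "complexity", "estimator": "approximate_entropy"},
}


def enumerate_routes(outcome_spaces=None, probabilities_estimators=None,
                     information_measures=None, discrete_estimators=None,
                     differential_estimators=None,
                     complexity_estimators=None) -> dict:
    """Count the computable estimation routes from the component catalogs.

    PMF routes: each count-based space works with every probabilities
    estimator, each weight-based one only with relative amounts.
    Discrete-measure routes: every measure with both generic estimators
    plus the Shannon-specific ones.  Total discrete measures = product of
    the two; differential and complexity routes add on top, plus the two
    probabilities functions (probabilities / all-probabilities) per PMF
    route.
    """
    spaces = OUTCOME_SPACES if outcome_spaces is None else outcome_spaces
    prob = (PROBABILITIES_ESTIMATORS if probabilities_estimators is None
            else probabilities_estimators)
    meas = (INFORMATION_MEASURES if information_measures is None
            else information_measures)
    disc = (DISCRETE_ESTIMATORS if discrete_estimators is None
            else discrete_estimators)
    diff = (DIFFERENTIAL_ESTIMATORS if differential_estimators is None
            else differential_estimators)
    cx = (COMPLEXITY_ESTIMATORS if complexity_estimators is None
          else complexity_estimators)

    n_count_spaces = sum(1 for e in spaces.values() if e.count_based)
    n_weight_spaces = len(spaces) - n_count_spaces
    pmf_routes = n_count_spaces * len(prob) + n_weight_spaces

    n_generic = sum(1 for _, kind in disc.values() if kind == "generic")
    n_shannon_specific = sum(1 for _, kind in disc.values() if kind == "shannon")
    discrete_measure_routes = len(meas) * n_generic + n_shannon_specific

    differential_routes = sum(len(supported) for _, supported in diff.values())

    total_discrete = pmf_routes * discrete_measure_routes
    probabilities_measures = 2 * pmf_routes
    grand_total = (total_discrete + differential_routes + len(cx)
                   + probabilities_measures)
    return {
        "outcome_spaces": len(spaces),
        "count_based_outcome_spaces": n_count_spaces,
        "probabilities_estimators": len(prob),
        "pmf_routes": pmf_routes,
        "information_measures": len(meas),
        "discrete_measure_routes": discrete_measure_routes,
        "total_discrete_measures": total_discrete,
        "differential_routes": differential_routes,
        "complexity_estimators": len(cx),
        "probabilities_measures": probabilities_measures,
        "grand_total": grand_total,
    }


def _resolve(catalog: dict, name: str, what: str):
    if name not in catalog:
        raise KeyError(
            f"unknown {what} {name!r}; valid names: {', '.join(sorted(catalog))}"
        )
    return catalog[name]


def _filter_kwargs(cls, params: dict) -> dict:
    import dataclasses as _dc
    if _dc.is_dataclass(cls):
        names = {f.name for f in _dc.fields(cls)}
        return {k: v for k, v in params.items() if k in names and v is not None}
    return {}


def resolve_outcome_space(name: str, **params) -> _os.OutcomeSpace:
    entry = _resolve(OUTCOME_SPACES, name, "outcome space")
    return entry.factory(**_filter_kwargs(entry.factory, params))


def resolve_measure(name: str, **params) -> _ms.InformationMeasure:
    cls = _resolve(INFORMATION_MEASURES, name, "information measure")
    return cls(**_filter_kwargs(cls, params))


def resolve_discrete_estimator(name: str):
    cls, _ = _resolve(DISCRETE_ESTIMATORS, name, "discrete estimator")
    return cls()


def resolve_probabilities_estimator(name: str, **params):
    cls = _resolve(PROBABILITIES_ESTIMATORS, name, "probabilities estimator")
    return cls(**_filter_kwargs(cls, params))


def resolve_complexity_estimator(name: str, **params):
    cls = _resolve(COMPLEXITY_ESTIMATORS, name, "complexity estimator")
    return cls(**_filter_kwargs(cls, params))
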