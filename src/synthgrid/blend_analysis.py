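"""Blend-level aggregation: interaction summaries and the cohesive-adhesive balance.

A binary powder blend of an active ingredient (API) and a carrier excipient
segregates or mixes depending on the balance between cohesion (API-API
binding) and adhesion (API-excipient binding). Each systematic search
contributes one binding energy -- the most negative total over all poses,
normalized per probe atom -- and searches are aggregated per interaction
type (cohesive A-A, adhesive A-B, cohesive B-B) into means, standard
deviations and component decompositions. The verdict:

* cohesion stronger than adhesion beyond a margin -> cohesively balanced
  blend, segregation of the API from the carrier predicted;
* otherwise -> adhesively balanced blend, the minor component disperses
  across the carrier surface.

Energies are kept in kcal/atom internally and echoed in kJ/atom
(1 kcal = 4.184 kJ) at reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .forcefield import EnergyBreakdown
from .grid_search import EnergyHistogram, SearchResult

KCAL_TO_KJ = 4.184

__all__ = [
    "BalanceVerdict",
    "GaussianFit",
    "KCAL_TO_KJ",
    "area_weighted_energy",
    "classify_balance",
    "convert_units",
    "display_round",
    "gaussian_fit",
    "summarize",
]


def convert_units(value_kcal: float) -> float:
    """kcal -> kJ (exactly linear; rounding only at display time)."""
    return value_kcal * KCAL_TO_KJ


def display_round(value: float, ndigits: int = 3) -> float:
    """Display rounding: 3 decimals, round-half-even."""
    return round(value, ndigits)


# --------------------------------------------------------------------------
# summaries


def summarize(results: Mapping[str, Sequence[SearchResult]]) -> pd.DataFrame:
    """Per-group mean/SD of binding energies plus component means.

    ``results`` maps a pair label (e.g. "API-API cohesive") to the searches
    in that group. The binding energy of a search is the best (minimum)
    per-atom total; SD is the sample standard deviation (n-1 denominator,
    0 for a single search). Empty groups are dropped with a warning.
    Columns carry both kcal/atom and kJ/atom.
    """
    rows = []
    for label, group in results.items():
        group = list(group)
        if not group:
            warnings.warn(f"group {label!r} has no searches; dropped")
            continue
        best = [r.best.per_atom for r in group]
        totals = [b.total for b in best]
        n = len(totals)
        # compensated sums so the statistics are independent of input order
        mean = math.fsum(totals) / n
        sd = math.sqrt(math.fsum((t - mean) ** 2 for t in totals) / (n - 1)) if n > 1 else 0.0
        row = {
            "pair": label,
            "n": len(group),
            "mean_kcal_per_atom": mean,
            "sd_kcal_per_atom": sd,
            "mean_kj_per_atom": convert_units(mean),
            "sd_kj_per_atom": convert_units(sd),
            "dispersive_kcal_per_atom": math.fsum(b.dispersive for b in best) / n,
            "electrostatic_kcal_per_atom": math.fsum(b.electrostatic for b in best) / n,
            "hbond_kcal_per_atom": math.fsum(b.hbond for b in best) / n,
            "polar_kcal_per_atom": math.fsum(b.polar for b in best) / n,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def area_weighted_energy(face_values: Sequence[float],
                         face_areas: Sequence[float]) -> float:
    """Surface-area weighted mean of per-face energies."""
    v = np.asarray(face_values, float)
    a = np.asarray(face_areas, float)
    if v.shape != a.shape:
        raise ValueError("face_values and face_areas must have equal length")
    if np.any(a < 0):
        raise ValueError("face areas must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("total face area must be positive")
    return float((v * a).sum() / total)


# --------------------------------------------------------------------------
# Gaussian fits of energy distributions


@dataclass(frozen=True)
class GaussianFit:
    mean: float
    sd: float
    amplitude: float
    residual_norm: float
    fallback: bool               # True when the histogram was too degenerate to fit


def _weighted_moments(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    w = counts / counts.sum()
    mean = float((w * centers).sum())
    var = float((w * (centers - mean) ** 2).sum())
    return mean, math.sqrt(max(var, 0.0))


def gaussian_fit(histogram: EnergyHistogram) -> GaussianFit:
    """Least-squares Gaussian fit to a binned energy distribution.

    Returns location, scale and the residual norm of the fit. Histograms
    with fewer than three nonempty bins cannot constrain a three-parameter
    Gaussian; they fall back to the weighted sample moments with the
    ``fallback`` flag set.
    """
    centers = histogram.centers
    counts = histogram.counts
    if histogram.n == 0:
        raise ValueError("cannot fit an empty histogram")
    mean0, sd0 = _weighted_moments(centers, counts)
    if histogram.n_nonempty_bins < 3 or sd0 == 0.0:
        return GaussianFit(mean0, sd0, float(counts.max()), 0.0, fallback=True)

    def model(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    p0 = (float(counts.max()), mean0, sd0)
    try:
        popt, _ = curve_fit(model, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError:
        return GaussianFit(mean0, sd0, p0[0], float("nan"), fallback=True)
    amp, mu, sigma = popt
    resid = float(np.linalg.norm(counts - model(centers, *popt)))
    return GaussianFit(float(mu), abs(float(sigma)), float(amp), resid, fallback=False)


# --------------------------------------------------------------------------
# the cohesive-adhesive balance


@dataclass(frozen=True)
class BalanceVerdict:
    """Outcome of the cohesive-adhesive comparison.

    ``classification`` is "cohesively-balanced" (segregation predicted) or
    "adhesively-balanced" (minor component disperses over the carrier).
    ``margin`` is mean(adhesive) - mean(cohesive) in kcal/atom: positive when
    cohesion is the stronger (more negative) interaction. ``ordering`` lists
    the pair labels from strongest (most negative mean) to weakest.
    """

    classification: str
    margin: float
    ordering: str
    segregation_predicted: bool


def classify_balance(summaries: pd.DataFrame, api_label: str,
                     excipient_label: str,
                     margin_threshold: float = 0.01) -> BalanceVerdict:
    """Classify a blend from its interaction summary table.

    ``summaries`` is the output of :func:`summarize`; rows are matched on the
    "pair" column. The cohesive entry is the API-API pair, the adhesive entry
    the API-excipient pair (both orderings averaged when present). Cohesion
    exceeding adhesion by more than ``margin_threshold`` (kcal/atom) predicts
    a cohesively balanced blend and hence segregation; otherwise -- adhesion
    dominant or the two within the margin -- the blend is adhesively
    balanced and the minor component is predicted to disperse.
    """
    if "pair" not in summaries.columns:
        raise KeyError("summary table lacks a 'pair' column")
    idx = {row["pair"]: row for _, row in summaries.iterrows()}

    def find(*fragments: str) -> list[float]:
        vals = [row["mean_kcal_per_atom"] for pair, row in idx.items()
                if all(f in pair for f in fragments)]
        return vals

    cohesive = find(f"{api_label}-{api_label}")
    adhesive = (find(f"{api_label}-{excipient_label}")
                + find(f"{excipient_label}-{api_label}"))
    if not cohesive:
        raise KeyError(f"summary table has no cohesive {api_label}-{api_label} entry")
    if not adhesive:
        raise KeyError(
            f"summary table has no adhesive {api_label}-{excipient_label} entry")
    mean_coh = float(np.mean(cohesive))
    mean_adh = float(np.mean(adhesive))
    margin = mean_adh - mean_coh  # > 0 when cohesion is more negative

    ordering = " > ".join(
        summaries.sort_values("mean_kcal_per_atom")["pair"].tolist())

    if margin > margin_threshold:
        return BalanceVerdict("cohesively-balanced", margin, ordering,
                              segregation_predicted=True)
    return BalanceVerdict("adhesively-balanced", margin, ordering,
                          segregation_predicted=False)
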