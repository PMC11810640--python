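"""Mixture modeling of Ks distributions for duplication-age analysis.

Peaks in the distribution of synonymous distances (Ks) among duplicate
pairs — especially segmental duplicates — are the classic signature of
whole-genome duplication events. This module fits normal or lognormal
mixtures by EM, selects the number of components by BIC over a
user-supplied candidate list (never automatically beyond it, since mixture
models on Ks data overcluster easily), and splits pairs into age groups at
component boundaries: either the intersection point of adjacent weighted
densities, or mean +/- N standard deviations around one component.

Lognormal fitting is normal EM on log-transformed values; peak positions
are reported at the lognormal mode exp(mu - sigma^2), because a "peak" in a
Ks plot is a density maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import DupmodeError

DEFAULT_EM_SEED = 2024  # fixed so published fits reproduce; overridable


@dataclass
class KsSample:
    """Ks values filtered to (min_ks, max_ks]."""

    values: np.ndarray
    min_ks: float = 0.01
    max_ks: float = 2.0

    @classmethod
    def from_values(cls, values, min_ks: float = 0.01,
                    max_ks: float = 2.0) -> "KsSample":
        arr = np.asarray(pd.Series(values).dropna(), dtype=float)
        arr = arr[(arr > min_ks) & (arr <= max_ks)]
        return cls(values=arr, min_ks=min_ks, max_ks=max_ks)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class KsMixtureModel:
    """Fitted mixture over a Ks sample.

    locations/scales are on the fitting scale (log scale for lognormal);
    components are sorted by increasing peak position on the Ks scale.
    ``loglik_path`` is the per-iteration log-likelihood trajectory of the
    winning EM run (non-decreasing by construction).
    """

    family: str
    k: int
    weights: np.ndarray
    locations: np.ndarray
    scales: np.ndarray
    log_likelihood: float
    bic: float
    n: int
    loglik_path: list[float] = field(default_factory=list)
    candidate_bics: dict[int, float] = field(default_factory=dict)

    @property
    def peaks(self) -> np.ndarray:
        """Component peak positions on the Ks scale (lognormal mode for the
        lognormal family)."""
        if self.family == "lognormal":
            return np.exp(self.locations - self.scales ** 2)
        return self.locations.copy()


@dataclass
class AgeBoundary:
    """How to cut the Ks axis into age groups.

    method ``intersection``: cutpoints at intersections of adjacent weighted
    component densities. method ``mean_sd``: one component's interval
    [peak - n_sd*sd, peak + n_sd*sd] on the fitting scale, remainder
    labeled "outside".
    """

    method: str = "intersection"
    n_sd: float = 2.0
    component: int = 0  # mean_sd only


def _log_norm_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return (-0.5 * math.log(2 * math.pi) - math.log(sigma)
            - 0.5 * ((x - mu) / sigma) ** 2)


def _em_run(x: np.ndarray, k: int, rng: np.random.Generator,
            tol: float = 1e-8, max_iter: int = 1000
            ) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray, float,
                                list[float], bool]]:
    """One EM run from a k-means-style seed; None on degeneracy."""
    n = len(x)
    centers = rng.choice(x, size=k, replace=False)
    for _ in range(10):  # Lloyd refinement of the seed
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            members = x[assign == j]
            if len(members):
                centers[j] = members.mean()
    mu = centers.astype(float)
    sigma = np.empty(k)
    lam = np.empty(k)
    global_sd = max(x.std(), 1e-3)
    for j in range(k):
        members = x[assign == j]
        sigma[j] = members.std() if len(members) > 1 else global_sd
        sigma[j] = max(sigma[j], 1e-3 * global_sd)
        lam[j] = max(len(members), 1) / n
    lam /= lam.sum()

    path: list[float] = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_comp = (np.log(lam)[None, :]
                    + np.stack([_log_norm_pdf(x, mu[j], sigma[j])
                                for j in range(k)], axis=1))
        log_total = logsumexp(log_comp, axis=1)
        ll = float(log_total.sum())
        if not np.isfinite(ll):
            return None
        if ll < prev_ll - 1e-7 * max(1.0, abs(prev_ll)):
            return None  # numerical breakdown; restart
        path.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_total[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            return None  # collapsed component
        lam = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, 1e-10))
        if np.any(sigma < 1e-6 * global_sd):
            return None
    return lam, mu, sigma, path[-1], path, converged


def fit_ks_mixture(sample: KsSample, k_candidates: Sequence[int],
                   family: str = "lognormal", n_restarts: int = 10,
                   seed: int = DEFAULT_EM_SEED, tol: float = 1e-8,
                   max_iter: int = 1000) -> KsMixtureModel:
    """Fit mixtures for each candidate k by EM and select the best by BIC.

    Each k gets ``n_restarts`` EM runs from k-means-style seeds under a
    fixed RNG seed; convergence tolerance is on the log-likelihood.
    """
    if not len(k_candidates):
        raise DupmodeError("k_candidates must not be empty")
    if family not in ("normal", "lognormal"):
        raise DupmodeError(f"unknown family {family!r}")
    values = np.asarray(sample.values, dtype=float)
    kmax = max(k_candidates)
    if len(values) < 10 * kmax:
        raise DupmodeError(
            f"sample size {len(values)} < 10 x max(k_candidates) ({10 * kmax})")
    if family == "lognormal":
        if np.any(values <= 0):
            raise DupmodeError("lognormal family requires positive values")
        x = np.log(values)
    else:
        x = values
    n = len(x)
    rng = np.random.default_rng(seed)
    best: Optional[KsMixtureModel] = None
    candidate_bics: dict[int, float] = {}
    for k in k_candidates:
        run_best = None
        for _ in range(n_restarts):
            res = _em_run(x, k, rng, tol=tol, max_iter=max_iter)
            if res is None or not res[5]:
                continue
            if run_best is None or res[3] > run_best[3]:
                run_best = res
        if run_best is None:
            warnings.warn(f"EM did not converge for k={k} in any restart",
                          stacklevel=2)
            continue
        lam, mu, sigma, ll, path, _ = run_best
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * math.log(n)
        candidate_bics[k] = bic
        model = KsMixtureModel(family=family, k=k, weights=lam,
                               locations=mu, scales=sigma,
                               log_likelihood=ll, bic=bic, n=n,
                               loglik_path=path)
        if best is None or bic < best.bic:
            best = model
    if best is None:
        raise DupmodeError("EM failed to converge for every candidate k")
    order = np.argsort(best.peaks)
    best.weights = best.weights[order]
    best.locations = best.locations[order]
    best.scales = best.scales[order]
    best.candidate_bics = candidate_bics
    return best


def component_intersection(model: KsMixtureModel, i: int, j: int
                           ) -> tuple[float, bool]:
    """Ks value between the peaks of adjacent components i < j where the
    weighted densities are equal.

    Solved in closed form (quadratic on the fitting scale; for the
    lognormal family the 1/x Jacobian cancels). Returns (x, fallback):
    if no root lies between the peaks, x is the peak midpoint and
    ``fallback`` is True (with a warning).
    """
    if not (0 <= i < j < model.k):
        raise DupmodeError(f"bad component indices ({i}, {j}) for k={model.k}")
    li, lj = model.weights[i], model.weights[j]
    mi, mj = model.locations[i], model.locations[j]
    si, sj = model.scales[i], model.scales[j]
    if math.isclose(mi, mj, abs_tol=1e-12) and math.isclose(si, sj,
                                                            abs_tol=1e-12):
        raise DupmodeError("identical components have no intersection")
    a = 1.0 / (2 * sj ** 2) - 1.0 / (2 * si ** 2)
    b = mi / si ** 2 - mj / sj ** 2
    c = (mj ** 2 / (2 * sj ** 2) - mi ** 2 / (2 * si ** 2)
         + math.log((li * sj) / (lj * si)))
    roots: list[float] = []
    if abs(a) < 1e-14:
        if abs(b) > 1e-14:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    peaks = model.peaks
    lo, hi = sorted((peaks[i], peaks[j]))
    xs = [math.exp(y) if model.family == "lognormal" else y for y in roots]
    inside = sorted(x for x in xs if lo < x < hi)
    if inside:
        return inside[0], False
    warnings.warn("no density intersection between component peaks; "
                  "falling back to peak midpoint", stacklevel=2)
    return (lo + hi) / 2.0, True


def cutpoints(model: KsMixtureModel) -> list[float]:
    """Intersection cutpoints between all adjacent component pairs."""
    return [component_intersection(model, i, i + 1)[0]
            for i in range(model.k - 1)]


@dataclass
class SplitResult:
    """Age-group assignment of duplicate pairs."""

    groups: dict[str, pd.DataFrame]
    n_excluded: int
    cutpoints: list[float]

    def sizes(self) -> dict[str, int]:
        return {label: len(df) for label, df in self.groups.items()}


def split_pairs_by_peak(pairs: pd.DataFrame, model: KsMixtureModel,
                        boundary: AgeBoundary = AgeBoundary(),
                        ks_column: str = "Ks") -> SplitResult:
    """Partition pairs into age groups by mixture-component boundaries.

    ``intersection``: k groups cut at adjacent-component intersections,
    boundary values going to the lower group. ``mean_sd``: the chosen
    component's [peak - n_sd*sd, peak + n_sd*sd] interval (fitting scale)
    vs "outside". Pairs with undefined Ks are excluded and counted.
    """
    defined = pairs[pairs[ks_column].notna()]
    n_excluded = len(pairs) - len(defined)
    ks = defined[ks_column].to_numpy(dtype=float)
    groups: dict[str, pd.DataFrame] = {}
    if boundary.method == "intersection":
        cuts = cutpoints(model)
        edges = [-np.inf] + list(cuts) + [np.inf]
        for g in range(model.k):
            mask = (ks > edges[g]) & (ks <= edges[g + 1])
            groups[f"group_{g + 1}"] = defined[mask]
        return SplitResult(groups=groups, n_excluded=n_excluded,
                           cutpoints=list(cuts))
    if boundary.method == "mean_sd":
        ci = boundary.component
        if not (0 <= ci < model.k):
            raise DupmodeError(f"component {ci} out of range for k={model.k}")
        mu, sd = model.locations[ci], model.scales[ci]
        lo_f, hi_f = mu - boundary.n_sd * sd, mu + boundary.n_sd * sd
        if model.family == "lognormal":
            lo, hi = math.exp(lo_f), math.exp(hi_f)
        else:
            lo, hi = lo_f, hi_f
        inside = (ks > lo) & (ks <= hi)
        groups[f"component_{ci + 1}"] = defined[inside]
        groups["outside"] = defined[~inside]
        return SplitResult(groups=groups, n_excluded=n_excluded,
                           cutpoints=[lo, hi])
    raise DupmodeError(f"unknown boundary method {boundary.method!r}")


def write_components(model: KsMixtureModel, path) -> None:
    """Component table TSV (family, k, weight, location, scale, peak_ks, bic)."""
    rows = [{"family": model.family, "k": model.k,
             "component": i + 1, "weight": model.weights[i],
             "location": model.locations[i], "scale": model.scales[i],
             "peak_ks": model.peaks[i], "bic": model.bic}
            for i in range(model.k)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_age_groups(result: SplitResult, path,
                     ks_column: str = "Ks") -> None:
    frames = []
    for label, df in result.groups.items():
        sub = df[["gene1", "gene2", ks_column]].copy()
        sub["group"] = label
        frames.append(sub)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["gene1", "gene2", ks_column, "group"]))
    out.to_csv(path, sep="\t", index=False)
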