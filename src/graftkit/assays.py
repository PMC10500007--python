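"""Binding-assay and selection-data analysis.

Implements the quantitative models used to characterise designed binders:

* one-site specific binding, ``y = bg + Bmax * x / (Kd + x)``, for
  cell-surface and plate titrations;
* the four-parameter logistic (4PL) curve for IC50/EC50 from competition
  and ELISA-style assays;
* the 1:1 biolayer interferometry (BLI) kinetic model, globally fit across
  analyte concentrations to shared kon/koff with Kd = koff/kon;
* log2 enrichment ratios for site-saturation mutagenesis (SSM) sorting
  experiments;
* the receptor-depletion mass balance used to validate titration conditions
  (ligand depletion kept under 5%);
* non-compartmental terminal half-life from the log-linear terminal phase
  of a concentration-time profile.

All fits are deterministic: nonlinear least squares from a fixed multi-start
grid, best residual wins, ties broken by grid order.  Standard errors come
from the Jacobian at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OneSiteFit",
    "FourPLFit",
    "KineticFit",
    "EnrichmentMap",
    "HalfLife",
    "DepletionCheck",
    "fit_one_site",
    "fit_4pl",
    "fit_bli_1to1",
    "enrichment_ratios",
    "check_ligand_depletion",
    "terminal_halflife",
]

AVOGADRO = 6.02214076e23


def _se_from_jacobian(jac: np.ndarray, residuals: np.ndarray, n_params: int) -> np.ndarray:
    """Asymptotic standard errors at a least-squares optimum."""
    n = len(residuals)
    dof = max(n - n_params, 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


# ---------------------------------------------------------------------------
# one-site specific binding
# ---------------------------------------------------------------------------


@dataclass
class OneSiteFit:
    kd: float
    bmax: float
    background: float
    se: dict[str, float]
    rss: float
    wide_interval: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.background + self.bmax * x / (self.kd + x)


def _kd_starts(conc: np.ndarray) -> list[float]:
    pos = conc[conc > 0]
    gm = float(np.exp(np.mean(np.log(pos))))
    return [float(pos.min()), gm, float(pos.max())]


def fit_one_site(conc, signal) -> OneSiteFit:
    """Fit a one-site specific binding curve, ``y = bg + Bmax x / (Kd + x)``.

    Requires at least four distinct concentrations.  Kd starts at the
    minimum, geometric mean and maximum of the positive concentrations; the
    fit with the lowest residual sum of squares wins.  If no concentration
    exceeds the fitted Kd the result is flagged ``wide_interval``.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    def resid(p):
        bg, bmax, lkd = p
        return bg + bmax * x / (np.exp(lkd) + x) - y

    best = None
    span = float(y.max() - y.min())
    for kd0 in _kd_starts(x):
        p0 = np.array([float(y.min()), span if span > 0 else 1.0, math.log(kd0)])
        sol = optimize.least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    bg, bmax, lkd = best.x
    kd = float(np.exp(lkd))
    se = _se_from_jacobian(best.jac, best.fun, 3)
    return OneSiteFit(
        kd=kd,
        bmax=float(bmax),
        background=float(bg),
        se={"background": se[0], "bmax": se[1], "kd": kd * se[2]},
        rss=float(2 * best.cost),
        wide_interval=bool(x.max() < kd),
    )


# ---------------------------------------------------------------------------
# four-parameter logistic
# ---------------------------------------------------------------------------


@dataclass
class FourPLFit:
    ic50: float
    top: float
    bottom: float
    hill: float
    se: dict[str, float]
    rss: float
    monotonicity_flag: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (x / self.ic50) ** self.hill)


def _monotonicity_violated(x: np.ndarray, y: np.ndarray) -> bool:
    """True when the dose-ordered response moves both up and down beyond noise."""
    order = np.argsort(x)
    ys = y[order]
    diffs = np.diff(ys)
    if len(diffs) < 2:
        return False
    sigma = np.median(np.abs(np.diff(diffs))) / 1.349 if len(diffs) > 2 else 0.0
    thresh = max(3.0 * sigma, 1e-12 * max(abs(ys.max()), 1.0))
    return bool((diffs > thresh).any() and (diffs < -thresh).any())


def fit_4pl(conc, response) -> FourPLFit:
    """Fit a four-parameter logistic curve for IC50/EC50 estimation.

    ``y = bottom + (top - bottom) / (1 + (x / ic50)^hill)``.  Orientation
    (rising or falling with dose) is auto-detected from the data trend;
    hill starts at {-2, -1, 1, 2} and ic50 at the minimum, geometric mean
    and maximum concentration.  The response at x = ic50 is the midpoint of
    top and bottom by construction.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    pos = x > 0

    def resid(p):
        bottom, top, lic50, hill = p
        return bottom + (top - bottom) / (1.0 + (x[pos] / np.exp(lic50)) ** hill) - y[pos]

    order = np.argsort(x)
    falling = y[order][-1] < y[order][0]
    top0 = float(y.max()) if falling else float(y.max())
    bottom0 = float(y.min())
    best = None
    for ic0 in _kd_starts(x):
        for hill0 in (-2.0, -1.0, 1.0, 2.0):
            p0 = np.array([bottom0, top0, math.log(ic0), hill0])
            sol = optimize.least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    bottom, top, lic50, hill = best.x
    se = _se_from_jacobian(best.jac, best.fun, 4)
    if top < bottom:
        # (bottom, top, hill) and (top, bottom, -hill) describe the same curve;
        # report the orientation with top as the larger response
        bottom, top = top, bottom
        hill = -hill
        se[0], se[1] = se[1], se[0]
    ic50 = float(np.exp(lic50))
    return FourPLFit(
        ic50=ic50,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        se={"bottom": se[0], "top": se[1], "ic50": ic50 * se[2], "hill": se[3]},
        rss=float(2 * best.cost),
        monotonicity_flag=_monotonicity_violated(x, y),
    )


# ---------------------------------------------------------------------------
# BLI 1:1 kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticFit:
    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float
    req: dict[float, float]  # equilibrium response per analyte concentration
    se: dict[str, float]
    rss: float
    koff_lower_bound_flag: bool = False

    @property
    def kd_kinetic(self) -> float:
        return self.koff / self.kon


def _bli_residuals(p, assoc, dissoc, concentrations):
    lkon, lkoff, lrmax = p
    kon, koff, rmax = np.exp(lkon), np.exp(lkoff), np.exp(lrmax)
    res = []
    for (ta, ya), (td, yd), c in zip(assoc, dissoc, concentrations):
        kobs = kon * c + koff
        req = rmax * kon * c / kobs
        ya_hat = req * (1.0 - np.exp(-kobs * ta))
        y0 = req * (1.0 - np.exp(-kobs * ta[-1]))
        yd_hat = y0 * np.exp(-koff * td)
        res.append(ya_hat - ya)
        res.append(yd_hat - yd)
    return np.concatenate(res)


def fit_bli_1to1(
    assoc_traces, dissoc_traces, concentrations, global_fit: bool = True
) -> KineticFit:
    """Global 1:1 fit of BLI association/dissociation traces.

    ``assoc_traces`` and ``dissoc_traces`` are sequences of (time, signal)
    arrays, one per analyte concentration (molar); dissociation times are
    measured from the start of dissociation.  Association follows
    ``Req (1 - exp(-(kon C + koff) t))`` with ``Req = Rmax kon C / (kon C +
    koff)``; dissociation decays from the association end-point with rate
    koff.  kon and koff (and Rmax) are shared across concentrations in the
    default global mode; ``global_fit=False`` fits each trace separately
    and averages the rate constants.

    A non-decaying dissociation signal sets ``koff_lower_bound_flag``.
    """
    assoc = [(np.asarray(t, float), np.asarray(y, float)) for t, y in assoc_traces]
    dissoc = [(np.asarray(t, float), np.asarray(y, float)) for t, y in dissoc_traces]
    concentrations = [float(c) for c in concentrations]
    if not (len(assoc) == len(dissoc) == len(concentrations)):
        raise ValueError("need one association and one dissociation trace per concentration")

    if not global_fit and len(concentrations) > 1:
        fits = [
            fit_bli_1to1([assoc[i]], [dissoc[i]], [concentrations[i]])
            for i in range(len(concentrations))
        ]
        kon = float(np.exp(np.mean([math.log(f.kon) for f in fits])))
        koff = float(np.exp(np.mean([math.log(f.koff) for f in fits])))
        req = {c: f.req[c] for f, c in zip(fits, concentrations)}
        return KineticFit(
            kon=kon,
            koff=koff,
            rmax=float(np.mean([f.rmax for f in fits])),
            req=req,
            se={},
            rss=float(sum(f.rss for f in fits)),
            koff_lower_bound_flag=any(f.koff_lower_bound_flag for f in fits),
        )

    # data-driven initial guesses, then a small fixed refinement grid
    td, yd = dissoc[0]
    decaying = yd[-1] < yd[0]
    pos = yd > 0
    if pos.sum() >= 3:
        slope = stats.linregress(td[pos], np.log(yd[pos])).slope
        koff0 = max(-slope, 1e-6)
    else:
        koff0 = 1e-3
    rmax0 = max(max(float(np.max(y)) for _, y in assoc) * 1.5, 1e-9)
    best = None
    for kon0 in (1e4, 1e5, 1e6):
        for koff_scale in (0.1, 1.0, 10.0):
            p0 = np.array([math.log(kon0), math.log(koff0 * koff_scale), math.log(rmax0)])
            sol = optimize.least_squares(
                _bli_residuals, p0, args=(assoc, dissoc, concentrations), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            if best is None or sol.cost < best.cost - 1e-18:
                best = sol
    lkon, lkoff, lrmax = best.x
    kon, koff, rmax = float(np.exp(lkon)), float(np.exp(lkoff)), float(np.exp(lrmax))
    se_log = _se_from_jacobian(best.jac, best.fun, 3)
    req = {c: rmax * kon * c / (kon * c + koff) for c in concentrations}
    return KineticFit(
        kon=kon,
        koff=koff,
        rmax=rmax,
        req=req,
        se={"kon": kon * se_log[0], "koff": koff * se_log[1], "rmax": rmax * se_log[2]},
        rss=float(2 * best.cost),
        koff_lower_bound_flag=not decaying,
    )


# ---------------------------------------------------------------------------
# SSM enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentMap:
    """log2 enrichment per variant between pre- and post-sort pools."""

    scores: dict
    pseudocount: float
    depth_pre: int
    depth_post: int
    unobserved: set = field(default_factory=set)
    matrix: pd.DataFrame | None = None


def enrichment_ratios(pre_counts: dict, post_counts: dict, pseudocount: float = 0.5) -> EnrichmentMap:
    """log2 enrichment of each variant between sequencing pools.

    ``E(v) = log2[(post_v + a) / sum(post + a)] - log2[(pre_v + a) / sum(pre + a)]``
    with pseudocount ``a`` applied to every variant of the union universe.
    Variants absent from both pools get a (finite) score but are listed as
    unobserved.  When variant keys are (position, substitution) tuples the
    scores are also arranged as a position x substitution matrix.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    universe = sorted(set(pre_counts) | set(post_counts), key=repr)
    pre = np.array([pre_counts.get(v, 0) for v in universe], dtype=float)
    post = np.array([post_counts.get(v, 0) for v in universe], dtype=float)
    if (pre < 0).any() or (post < 0).any():
        raise ValueError("counts must be non-negative")
    pre_tot = float((pre + pseudocount).sum())
    post_tot = float((post + pseudocount).sum())
    scores = {
        v: float(
            np.log2((post[i] + pseudocount) / post_tot) - np.log2((pre[i] + pseudocount) / pre_tot)
        )
        for i, v in enumerate(universe)
    }
    unobserved = {v for i, v in enumerate(universe) if pre[i] == 0 and post[i] == 0}
    matrix = None
    if universe and all(isinstance(v, tuple) and len(v) == 2 for v in universe):
        positions = sorted({v[0] for v in universe}, key=repr)
        subs = sorted({v[1] for v in universe}, key=repr)
        matrix = pd.DataFrame(
            [[scores.get((p, s), np.nan) for s in subs] for p in positions],
            index=positions,
            columns=subs,
        )
    return EnrichmentMap(
        scores=scores,
        pseudocount=pseudocount,
        depth_pre=int(pre.sum()),
        depth_post=int(post.sum()),
        unobserved=unobserved,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# ligand depletion
# ---------------------------------------------------------------------------


@dataclass
class DepletionCheck:
    depleted_fraction: float
    bound: float
    receptor_concentration: float
    passes: bool


def check_ligand_depletion(
    kd: float, receptor_sites: float, volume: float, conc: float
) -> DepletionCheck:
    """Mass-balance check that receptor binding does not deplete the ligand.

    ``kd`` and ``conc`` in molar, ``receptor_sites`` as a site count and
    ``volume`` in litres.  The bound ligand concentration solves the
    quadratic equilibrium mass balance; the check fails when the depleted
    fraction reaches 5% (the acceptable-condition rule is strictly under
    5%).
    """
    if min(kd, receptor_sites, volume, conc) <= 0:
        raise ValueError("all quantities must be positive")
    receptor = receptor_sites / (AVOGADRO * volume)
    s = receptor + conc + kd
    bound = (s - math.sqrt(s * s - 4.0 * receptor * conc)) / 2.0
    fraction = bound / conc
    return DepletionCheck(
        depleted_fraction=fraction,
        bound=bound,
        receptor_concentration=receptor,
        passes=bool(fraction + 1e-12 < 0.05),
    )


# ---------------------------------------------------------------------------
# terminal half-life
# ---------------------------------------------------------------------------


@dataclass
class HalfLife:
    lambda_z: float | None
    t_half: float | None
    indices: tuple[int, ...]
    r_squared: float | None
    defined: bool


def terminal_halflife(times, concentrations) -> HalfLife:
    """Non-compartmental terminal half-life from a concentration-time profile.

    The terminal phase is the suffix of at least three strictly declining
    positive concentrations that maximises the adjusted r-squared of the
    log-linear regression; ``t_half = ln 2 / lambda_z`` with lambda_z the
    negated regression slope.  Profiles with no declining suffix yield an
    undefined (flagged) result.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) != len(c):
        raise ValueError("times and concentrations must have equal length")
    n = len(t)
    order = np.argsort(t)
    t, c = t[order], c[order]
    best = None
    for start in range(0, n - 2):
        seg_t, seg_c = t[start:], c[start:]
        if (seg_c <= 0).any() or not (np.diff(seg_c) < 0).all():
            continue
        reg = stats.linregress(seg_t, np.log(seg_c))
        if reg.slope >= 0:
            continue
        k = len(seg_t)
        r2 = reg.rvalue**2
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if best is None or adj > best[0] + 1e-15:
            best = (adj, start, reg, r2)
    if best is None:
        return HalfLife(lambda_z=None, t_half=None, indices=(), r_squared=None, defined=False)
    adj, start, reg, r2 = best
    lam = -reg.slope
    return HalfLife(
        lambda_z=float(lam),
        t_half=float(math.log(2.0) / lam),
        indices=tuple(range(start, n)),
        r_squared=float(r2),
        defined=True,
    )
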