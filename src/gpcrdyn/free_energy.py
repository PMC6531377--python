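"""Bennett Acceptance Ratio (BAR) free-energy estimation from work samples.

An alchemical transformation from the ligand-bound (lambda = 0) to the
ligand-free (lambda = 1) system is split into windows; each window supplies
forward work samples W_f (measured 0 -> 1) and reverse work samples W_r
(measured 1 -> 0), in reduced units (k_B T = 1) or kcal/mol.  BAR combines
both directions into the minimum-variance estimate of the window free
energy dG by solving the self-consistent equation

    sum_i fermi(M + W_f,i - dG)  =  sum_j fermi(-M + W_r,j + dG),
    fermi(x) = 1 / (1 + exp(x)),   M = ln(n_f / n_r),

by bracketed root finding.  The asymptotic standard error uses Bennett's
variance estimator; window results add, with errors combined in quadrature.

This module only consumes externally supplied work samples — it never runs
the alchemical simulations that produce them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

__all__ = [
    "WindowWork",
    "FreeEnergyResult",
    "KB_KCAL",
    "bar_window",
    "bar_total",
    "exponential_averaging",
    "to_kcal_per_mol",
]

KB_KCAL = 0.0019872041        # kcal/(mol K)
DEFAULT_TEMPERATURE = 310.0   # K, physiological simulation temperature


@dataclass
class WindowWork:
    """Forward/reverse work samples of one lambda window."""

    index: int
    forward: np.ndarray
    reverse: np.ndarray
    units: str = "reduced"        # "reduced" (k_B T) or "kcal/mol"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.reverse = np.asarray(self.reverse, dtype=float)
        if self.forward.size == 0 or self.reverse.size == 0:
            raise ValueError("both work sample sets must be nonempty")
        if self.units not in ("reduced", "kcal/mol"):
            raise ValueError("units must be 'reduced' or 'kcal/mol'")

    def reduced(self) -> "WindowWork":
        if self.units == "reduced":
            return self
        beta = 1.0 / (KB_KCAL * self.temperature)
        return WindowWork(self.index, self.forward * beta,
                          self.reverse * beta, "reduced", self.temperature)


@dataclass
class WindowResult:
    index: int
    dg: float
    se: float
    se_reliable: bool = True


@dataclass
class FreeEnergyResult:
    windows: list[WindowResult] = field(default_factory=list)
    units: str = "reduced"

    @property
    def total_dg(self) -> float:
        return float(sum(w.dg for w in self.windows))

    @property
    def total_se(self) -> float:
        return float(np.sqrt(sum(w.se ** 2 for w in self.windows)))


def _bar_imbalance(dg: float, wf: np.ndarray, wr: np.ndarray,
                   m: float) -> float:
    """Difference of the two Fermi sums; root at the BAR estimate."""
    return float(expit(-(m + wf - dg)).sum() - expit(-(-m + wr + dg)).sum())


def bar_window(w: WindowWork, tol: float = 1e-10,
               max_iter: int = 10_000) -> WindowResult:
    """Solve the Bennett self-consistent equation for one window.

    Returns the window dG and its asymptotic standard error (both in the
    window's reduced units).  When forward and reverse work distributions
    barely overlap, the converged value is still returned but the SE is
    flagged unreliable via a warning and ``se_reliable=False``.
    """
    red = w.reduced()
    wf, wr = red.forward, red.reverse
    nf, nr = wf.size, wr.size
    m = float(np.log(nf / nr))

    # deterministic work: the estimate is exact, no root finding needed
    if wf.std() == 0.0 and wr.std() == 0.0 and np.isclose(wf[0], -wr[0]):
        return WindowResult(w.index, float(wf[0]), 0.0)

    lo = float(min(wf.min(), -wr.max())) - 10.0
    hi = float(max(wf.max(), -wr.min())) + 10.0
    # the imbalance is monotone increasing in dg; widen until it brackets
    span = hi - lo if hi > lo else 1.0
    while _bar_imbalance(lo, wf, wr, m) > 0.0:
        lo -= span
    while _bar_imbalance(hi, wf, wr, m) < 0.0:
        hi += span
    dg = brentq(_bar_imbalance, lo, hi, args=(wf, wr, m),
                xtol=tol, maxiter=max_iter)

    # Bennett's asymptotic variance: var = (1/nf)(<f^2>/<f>^2 - 1)_F
    #                                   + (1/nr)(<f^2>/<f>^2 - 1)_R
    ff = expit(-(m + wf - dg))
    fr = expit(-(-m + wr + dg))
    se_reliable = True
    with np.errstate(divide="ignore", invalid="ignore"):
        var = ((ff ** 2).mean() / ff.mean() ** 2 - 1.0) / nf \
            + ((fr ** 2).mean() / fr.mean() ** 2 - 1.0) / nr
    if not np.isfinite(var) or ff.mean() < 1e-12 or fr.mean() < 1e-12:
        warnings.warn(f"window {w.index}: forward/reverse work distributions "
                      "barely overlap; SE estimate unreliable", stacklevel=2)
        se_reliable = False
        var = max(var, 0.0) if np.isfinite(var) else 0.0
    return WindowResult(w.index, float(dg), float(np.sqrt(max(var, 0.0))),
                        se_reliable)


def bar_total(windows: list[WindowWork], **kwargs) -> FreeEnergyResult:
    """Total free energy over ordered lambda windows.

    dG_total = sum of window dGs; SE combined in quadrature.  All windows
    must carry the same units flag.
    """
    if not windows:
        raise ValueError("no windows supplied")
    units = {w.units for w in windows}
    if len(units) > 1:
        raise ValueError(f"inconsistent work units across windows: {units}")
    res = FreeEnergyResult(units="reduced")
    for w in windows:
        res.windows.append(bar_window(w, **kwargs))
    return res


def exponential_averaging(work: np.ndarray) -> float:
    """One-sided free-energy perturbation estimate (reduced units).

    dG = -ln < exp(-W) >; higher-variance and more biased than BAR — kept
    as the comparison baseline.
    """
    work = np.asarray(work, dtype=float)
    if work.size == 0:
        raise ValueError("empty work sample set")
    return float(-(logsumexp(-work) - np.log(work.size)))


def to_kcal_per_mol(dg_reduced: float,
                    temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a reduced (k_B T) free energy to kcal/mol at a temperature."""
    return dg_reduced * KB_KCAL * temperature
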