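"""Quantification of the cell-based assays.

Dose-response curves (Ca2+ mobilization, beta-arrestin recruitment,
antagonist inhibition) are fit with the four-parameter logistic (4PL)
sigmoid on log10 dose:

    y(x) = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 x) * hill))

Agonist curves have hill > 0 (increasing in dose); antagonist curves are
fit with hill < 0 and report the midpoint as an IC50.  Fits are
least-squares over all individual replicates with a data-driven start
plus seeded jittered restarts; standard errors come from the
Jacobian-based covariance.

Also provided: the cell-surface binding ratio F_anti-HA / F_anti-Flag,
the Ca2+ RFU after/before ratio, and 2^-dCt relative expression with
knockdown fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize


def four_pl(x, bottom: float, top: float, log_ec50: float, hill: float):
    """Four-parameter logistic response at concentration ``x`` (nM).

    Monotone increasing in x for hill > 0, decreasing for hill < 0;
    equals (top + bottom)/2 at x = EC50.  Raises for x <= 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - np.log10(x)) * hill))


@dataclass(frozen=True)
class DoseResponseDataset:
    """Dose series with replicate responses.

    ``doses`` are strictly increasing concentrations in nM (>= 4 of
    them); ``responses[i]`` holds the replicates measured at
    ``doses[i]``.  ``mode`` is 'agonist' or 'antagonist'; antagonist
    datasets may carry the fixed agonist dose used during the
    inhibition series.
    """

    doses: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]
    mode: str = "agonist"
    fixed_agonist_dose_nM: float | None = None

    def __post_init__(self):
        if self.mode not in ("agonist", "antagonist"):
            raise ValueError("mode must be 'agonist' or 'antagonist'")
        if len(self.doses) < 4:
            raise ValueError("need at least 4 distinct doses")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive (nM)")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if len(self.responses) != len(self.doses):
            raise ValueError("one replicate list per dose required")
        for reps in self.responses:
            if len(reps) == 0:
                raise ValueError("each dose needs at least one replicate")
            if not all(math.isfinite(r) for r in reps):
                raise ValueError("responses must be finite")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, response) arrays with one row per replicate."""
        xs, ys = [], []
        for d, reps in zip(self.doses, self.responses):
            xs.extend([d] * len(reps))
            ys.extend(reps)
        return np.array(xs), np.array(ys)

    def dose_means(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.responses])


@dataclass(frozen=True)
class FitResult:
    """Fitted 4PL parameters with uncertainty and diagnostics.

    ``ec50_or_ic50`` is in nM (10^logEC50); standard errors are
    Jacobian-based asymptotic SEs (the EC50 SE via the delta method).
    ``direction_mismatch`` is set when the observed dose trend
    contradicts the requested mode — treat the parameters as unreliable
    in that case.
    """

    ec50_or_ic50: float
    hill: float
    top: float
    bottom: float
    se_ec50: float
    se_hill: float
    se_top: float
    se_bottom: float
    converged: bool
    rss: float
    mode: str = "agonist"
    direction_mismatch: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "ec50_or_ic50_nM": self.ec50_or_ic50,
            "hill": self.hill,
            "top": self.top,
            "bottom": self.bottom,
            "se_ec50_nM": self.se_ec50,
            "se_hill": self.se_hill,
            "se_top": self.se_top,
            "se_bottom": self.se_bottom,
            "converged": self.converged,
            "rss": self.rss,
            "direction_mismatch": self.direction_mismatch,
            "message": self.message,
        }


def _residuals(params, logx, y):
    bottom, top, log_ec50, hill = params
    pred = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logx) * hill))
    return pred - y


def _jacobian(params, logx, y):
    bottom, top, log_ec50, hill = params
    u = 10.0 ** ((log_ec50 - logx) * hill)
    denom = (1.0 + u) ** 2
    f = 1.0 / (1.0 + u)
    ln10 = math.log(10.0)
    d_bottom = 1.0 - f
    d_top = f
    d_log = -(top - bottom) * u * hill * ln10 / denom
    d_hill = -(top - bottom) * u * (log_ec50 - logx) * ln10 / denom
    return np.column_stack([d_bottom, d_top, d_log, d_hill])


def fit_dose_response(
    data: DoseResponseDataset,
    hill_fixed: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Least-squares 4PL fit on log10 dose over all replicates.

    Initialization takes bottom/top from the extreme dose-group means
    and logEC50 from the dose whose mean lies nearest the midpoint,
    then adds ``n_restarts`` seeded jittered starts and keeps the best
    solution.  Antagonist mode constrains hill < 0 and reports the
    midpoint as an IC50.  Non-convergence of every start returns
    ``converged=False`` with diagnostics, never a silent number.
    """
    x, y = data.flat()
    logx = np.log10(x)
    means = data.dose_means()
    antagonist = data.mode == "antagonist"

    # direction check: Spearman-like trend of dose-group means vs dose order
    trend = float(np.corrcoef(np.arange(len(means)), means)[0, 1]) if len(means) > 1 else 0.0
    expected_sign = -1.0 if antagonist else 1.0
    direction_mismatch = bool(trend * expected_sign < 0)

    lo, hi = float(means.min()), float(means.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    mid = 0.5 * (lo + hi)
    log_mid = float(np.log10(data.doses[int(np.argmin(np.abs(means - mid)))]))

    if antagonist:
        hill0, hill_bounds = -1.0, (-10.0, -1e-3)
    else:
        hill0, hill_bounds = 1.0, (1e-3, 10.0)
    if hill_fixed:
        hill_bounds = (hill0 - 1e-9, hill0 + 1e-9)

    logx_lo, logx_hi = float(logx.min()) - 2.0, float(logx.max()) + 2.0
    lower = [lo - 2 * span, lo - 2 * span, logx_lo, hill_bounds[0]]
    upper = [hi + 2 * span, hi + 2 * span, logx_hi, hill_bounds[1]]

    starts = [np.array([lo, hi, log_mid, hill0])]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        jitter = np.array(
            [
                lo + 0.2 * span * rng.standard_normal(),
                hi + 0.2 * span * rng.standard_normal(),
                log_mid + rng.normal(0, 1.0),
                hill0 * float(np.exp(rng.normal(0, 0.3))),
            ]
        )
        starts.append(np.clip(jitter, np.array(lower) + 1e-9, np.array(upper) - 1e-9))

    best = None
    messages = []
    for start in starts:
        try:
            sol = optimize.least_squares(
                _residuals,
                start,
                jac=_jacobian,
                bounds=(lower, upper),
                args=(logx, y),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            messages.append(str(exc))
            continue
        if not sol.success:
            messages.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FitResult(
            ec50_or_ic50=float("nan"),
            hill=float("nan"),
            top=float("nan"),
            bottom=float("nan"),
            se_ec50=float("nan"),
            se_hill=float("nan"),
            se_top=float("nan"),
            se_bottom=float("nan"),
            converged=False,
            rss=float("nan"),
            mode=data.mode,
            direction_mismatch=direction_mismatch,
            message="; ".join(messages) or "no start converged",
        )

    bottom_f, top_f, log_ec50_f, hill_f = best.x
    rss = float(2 * best.cost)
    n, p = len(y), 4 - (1 if hill_fixed else 0)
    dof = max(n - p, 1)
    sigma2 = rss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, float("nan"))
    ec50 = float(10.0 ** log_ec50_f)
    se_ec50 = float(math.log(10.0) * ec50 * se[2])

    return FitResult(
        ec50_or_ic50=ec50,
        hill=float(hill_f),
        top=float(top_f),
        bottom=float(bottom_f),
        se_ec50=se_ec50,
        se_hill=float(se[3]),
        se_top=float(se[1]),
        se_bottom=float(se[0]),
        converged=True,
        rss=rss,
        mode=data.mode,
        direction_mismatch=direction_mismatch,
        message="" if not direction_mismatch else (
            "observed dose trend contradicts the requested mode; "
            "parameters are unreliable"
        ),
    )


def dataset_from_frame(frame, mode: str = "agonist") -> DoseResponseDataset:
    """Build a dataset from a long-format table with dose_nM and response columns."""
    if "dose_nM" not in frame.columns or "response" not in frame.columns:
        raise ValueError("table must have 'dose_nM' and 'response' columns")
    doses = sorted(frame["dose_nM"].unique())
    responses = tuple(
        tuple(float(v) for v in frame.loc[frame["dose_nM"] == d, "response"])
        for d in doses
    )
    return DoseResponseDataset(
        doses=tuple(float(d) for d in doses), responses=responses, mode=mode
    )


def rfu_ratio(before: Sequence[float], after: Sequence[float]) -> float:
    """Ca2+ response ratio: mean(after window) / mean(before window)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("both windows must be nonempty")
    baseline = float(before.mean())
    if baseline <= 0:
        raise ValueError("baseline mean must be positive")
    return float(after.mean()) / baseline


@dataclass(frozen=True)
class CellFluorescenceRecord:
    """Per-cell mean fluorescence in the anti-HA and anti-Flag channels."""

    cell_id: str
    f_anti_ha: float
    f_anti_flag: float

    def __post_init__(self):
        if self.f_anti_ha < 0 or self.f_anti_flag < 0:
            raise ValueError("fluorescence must be nonnegative")


@dataclass(frozen=True)
class RatioSummary:
    ratios: tuple[float, ...]
    mean: float
    sem: float
    n: int


def binding_ratio(cells: Sequence[CellFluorescenceRecord]) -> RatioSummary:
    """Per-cell F_anti-HA / F_anti-Flag ratios with group mean +/- SEM."""
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    ratios = []
    for c in cells:
        if c.f_anti_flag == 0:
            raise ValueError(f"cell {c.cell_id!r}: zero anti-Flag signal")
        ratios.append(c.f_anti_ha / c.f_anti_flag)
    arr = np.array(ratios)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return RatioSummary(
        ratios=tuple(ratios), mean=float(arr.mean()), sem=sem, n=len(arr)
    )


def delta_ct_expression(ct_target: float, ct_ref: float) -> float:
    """Relative expression by the 2^-dCt method (target vs reference gene)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_ref)


def knockdown_fraction(expr_sh: float, expr_scramble: float) -> float:
    """Fraction of expression lost in the shRNA condition vs scramble."""
    if expr_scramble <= 0:
        raise ValueError("scramble expression must be positive")
    return 1.0 - expr_sh / expr_scramble
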