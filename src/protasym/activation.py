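"""Hill-equation dose-response fitting: EC50 and Hill slope with uncertainties."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import InsufficientDataError, ParameterError

__all__ = ["DoseResponse", "HillFit", "hill_model", "fit_hill", "compare_activation"]


@dataclasses.dataclass
class DoseResponse:
    """Replicate activation measurements over a concentration series (nM)."""

    concentration: np.ndarray
    response: np.ndarray
    replicate_id: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        if not (
            len(self.concentration) == len(self.response) == len(self.replicate_id)
        ):
            raise ParameterError("concentration/response/replicate lengths differ")
        if np.any(self.concentration <= 0):
            raise ParameterError("concentrations must be positive")

    @property
    def n_distinct_concentrations(self) -> int:
        return len(np.unique(self.concentration))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_nM": self.concentration,
                "replicate": self.replicate_id,
                "response": self.response,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponse":
        return cls(
            concentration=df["concentration_nM"].to_numpy(),
            response=df["response"].to_numpy(),
            replicate_id=df["replicate"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "DoseResponse":
        return cls.from_frame(pd.read_csv(path))


@dataclasses.dataclass
class HillFit:
    ec50: float
    hill_n: float
    y0: float
    ymax: float
    se_ec50: float
    se_hill: float
    converged: bool
    residual_ss: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "ec50_nM": self.ec50,
            "hill_n": self.hill_n,
            "y0": self.y0,
            "ymax": self.ymax,
            "se_ec50_nM": self.se_ec50,
            "se_hill": self.se_hill,
            "converged": self.converged,
        }


def hill_model(
    c: np.ndarray | float,
    ec50: float,
    hill_n: float,
    y0: float = 0.0,
    ymax: float = 1.0,
) -> np.ndarray | float:
    """y = y0 + (ymax - y0) * c^n / (ec50^n + c^n), evaluated in the log
    domain so large n*ln(c) cannot overflow."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ParameterError("concentrations must be positive")
    if ec50 <= 0:
        raise ParameterError("ec50 must be positive")
    # c^n/(ec50^n + c^n) = expit(n * (ln c - ln ec50))
    frac = expit(hill_n * (np.log(c_arr) - np.log(ec50)))
    out = y0 + (ymax - y0) * frac
    return out if np.ndim(c) else float(out)


def fit_hill(data: DoseResponse, init: dict | None = None) -> HillFit:
    """Nonlinear least squares in (log10 ec50, n, y0, ymax).

    Standard errors come from the residual-variance-scaled inverse Gauss-
    Newton curvature at the optimum; ``converged`` reflects the optimizer's
    own status rather than being assumed.
    """
    if data.n_distinct_concentrations < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {data.n_distinct_concentrations}"
        )
    c = data.concentration
    y = data.response

    init = init or {}
    y0_init = init.get("y0", float(np.min(y)))
    ymax_init = init.get("ymax", float(np.max(y)))
    mid = 0.5 * (y0_init + ymax_init)
    # default EC50 guess: concentration whose mean response is nearest midpoint
    uniq = np.unique(c)
    means = np.array([y[c == u].mean() for u in uniq])
    ec50_init = init.get("ec50", float(uniq[np.argmin(np.abs(means - mid))]))
    n_init = init.get("hill_n", 1.0)

    def residuals(p):
        log_ec50, n, y0, ymax = p
        return hill_model(c, 10.0**log_ec50, n, y0, ymax) - y

    p0 = np.array([np.log10(ec50_init), n_init, y0_init, ymax_init])
    sol = least_squares(residuals, p0, method="lm", max_nfev=10000)

    log_ec50, n, y0, ymax = sol.x
    ec50 = 10.0**log_ec50
    dof = max(len(y) - 4, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se_log_ec50 = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_hill = float(np.sqrt(max(cov[1, 1], 0.0)))
        se_ec50 = ec50 * np.log(10.0) * se_log_ec50  # delta method
    except np.linalg.LinAlgError:
        se_ec50 = se_hill = float("nan")
    return HillFit(
        ec50=float(ec50),
        hill_n=float(n),
        y0=float(y0),
        ymax=float(ymax),
        se_ec50=se_ec50,
        se_hill=se_hill,
        converged=bool(sol.success),
        residual_ss=float(np.sum(sol.fun**2)),
    )


def compare_activation(fits: list[HillFit], labels: list[str]) -> pd.DataFrame:
    """Side-by-side fit table with EC50 ratios relative to the first entry.

    ``easier_to_activate`` marks fits with lower EC50 than the first fit;
    ``reduced_cooperativity`` marks Hill slopes below 1.
    """
    if len(fits) < 2:
        raise InsufficientDataError("need at least 2 fits to compare")
    if len(fits) != len(labels):
        raise ParameterError("one label per fit required")
    ref = fits[0]
    rows = []
    for label, fit in zip(labels, fits):
        rows.append(
            {
                "label": label,
                "ec50_nM": fit.ec50,
                "se_ec50_nM": fit.se_ec50,
                "hill_n": fit.hill_n,
                "se_hill": fit.se_hill,
                "ec50_ratio_vs_first": ref.ec50 / fit.ec50,
                "easier_to_activate": fit.ec50 < ref.ec50,
                "reduced_cooperativity": fit.hill_n < 1.0,
            }
        )
    return pd.DataFrame(rows)
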