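"""Saturation-binding model fitting for aptamer affinity (Kd) estimation.

The total binding signal of a fluorophore-labelled aptamer at concentration
``X`` (nM) is modelled as specific one-site saturation plus a linear
nonspecific component and a constant background::

    response(X) = Bmax * X / (X + Kd) + NS * X + Background

where ``Bmax`` is the maximal specific signal, ``Kd`` the dissociation
constant (nM; the concentration of half-maximal specific binding), ``NS``
the nonspecific slope (signal per nM) and ``Background`` the signal floor.
The response is typically a flow-cytometry median fluorescence intensity.

The model is exposed statsmodels-style: build a
:class:`SaturationBindingModel` from a tidy dose-response table, call
``fit()``, and read estimates, standard errors and diagnostics off the
returned :class:`BindingFitResult` (``summary()`` prints a small report).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingModelParams",
    "SaturationBindingModel",
    "BindingFitResult",
    "model_response",
    "estimate_background",
    "fit_kd",
    "pool_kd",
]

_PARAM_NAMES = ("Bmax", "Kd", "NS", "Background")


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the one-site total binding model."""

    Bmax: float
    Kd: float
    NS: float = 0.0
    Background: float = 0.0

    def __post_init__(self) -> None:
        if self.Bmax < 0:
            raise ValueError("Bmax must be >= 0")
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if self.NS < 0:
            raise ValueError("NS must be >= 0")
        if self.Background < 0:
            raise ValueError("Background must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.Bmax, self.Kd, self.NS, self.Background])


def model_response(X, params: BindingModelParams):
    """Evaluate the saturation model at dose(s) ``X`` (nM)."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("doses must be >= 0")
    out = params.Bmax * X / (X + params.Kd) + params.NS * X + params.Background
    return float(out) if out.ndim == 0 else out


def estimate_background(controls: pd.DataFrame) -> tuple[float, float, list[str]]:
    """Estimate (Background, NS prior) from control rows.

    ``controls`` needs columns ``dose_nM``, ``response`` and ``control_type``
    with values ``no_aptamer`` (zero-aptamer blanks) and/or ``library``
    (random-library incubation at a known dose).  Background is the mean of
    the zero-aptamer responses; the NS prior is
    ``(library response - Background) / library dose`` when a library control
    exists, else 0.  Returns a list of warning strings alongside.
    """
    notes: list[str] = []
    if controls is None or len(controls) == 0:
        return 0.0, 0.0, ["no control records: Background prior set to 0"]
    blanks = controls[controls["control_type"] == "no_aptamer"]
    if len(blanks):
        background = float(blanks["response"].mean())
    else:
        background = 0.0
        notes.append("no zero-aptamer controls: Background prior set to 0")
    library = controls[controls["control_type"] == "library"]
    ns_prior = 0.0
    if len(library):
        dose = float(library["dose_nM"].mean())
        if dose > 0:
            ns_prior = max(
                0.0, (float(library["response"].mean()) - background) / dose
            )
        else:
            notes.append("library control has dose 0: NS prior set to 0")
    return background, ns_prior, notes


class SaturationBindingModel:
    """Nonlinear least-squares fit of the total binding model.

    Parameters
    ----------
    data : DataFrame
        Tidy dose-response table with columns ``dose_nM`` and ``response``;
        optional ``replicate`` and ``control_type`` columns.  Rows whose
        ``control_type`` is ``no_aptamer`` or ``library`` are treated as
        controls (used for initialisation) and excluded from the fitted
        points, except zero-aptamer blanks which enter as dose-0 points.
    weights : array-like, optional
        Per-point weights for weighted least squares (default unweighted).
    """

    def __init__(self, data: pd.DataFrame, weights=None):
        data = data.copy()
        if "control_type" not in data.columns:
            data["control_type"] = ""
        data["control_type"] = data["control_type"].fillna("")
        if "replicate" not in data.columns:
            data["replicate"] = 0
        missing = {"dose_nM", "response"} - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required columns {sorted(missing)}")
        if not np.isfinite(data["response"].to_numpy(dtype=float)).all():
            raise ValueError("responses must be finite")
        if (data["dose_nM"] < 0).any():
            raise ValueError("doses must be >= 0")
        self.data = data
        self.controls = data[data["control_type"].isin(["no_aptamer", "library"])]
        fit_rows = data[~data["control_type"].isin(["library"])].copy()
        # zero-aptamer blanks are genuine dose-0 observations of Background
        fit_rows.loc[fit_rows["control_type"] == "no_aptamer", "dose_nM"] = 0.0
        self.fit_data = fit_rows
        n_pos = fit_rows.loc[fit_rows["dose_nM"] > 0, "dose_nM"].nunique()
        if n_pos < 3:
            raise ValueError(
                f"need >= 3 distinct positive doses to fit, got {n_pos}"
            )
        self.weights = None if weights is None else np.asarray(weights, float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "SaturationBindingModel":
        return cls(data, **kw)

    def _initial_guess(self) -> np.ndarray:
        y = self.fit_data["response"].to_numpy(float)
        x = self.fit_data["dose_nM"].to_numpy(float)
        background0, ns0, _ = estimate_background(self.controls)
        bmax0 = max(y.max() - y.min(), 1e-6)
        kd0 = float(np.median(x[x > 0]))
        return np.array([bmax0, kd0, ns0, background0])

    def predict(self, params: BindingModelParams, X=None):
        if X is None:
            X = self.fit_data["dose_nM"].to_numpy(float)
        return model_response(X, params)

    def fit(
        self,
        start: BindingModelParams | Sequence[float] | None = None,
        max_iter: int = 10_000,
        xtol: float = 1e-8,
    ) -> "BindingFitResult":
        x = self.fit_data["dose_nM"].to_numpy(float)
        y = self.fit_data["response"].to_numpy(float)
        w = np.ones_like(y) if self.weights is None else np.sqrt(self.weights)

        if np.ptp(y) == 0.0:
            # flat data: Background carries everything, Kd is meaningless
            params = BindingModelParams(0.0, self._initial_guess()[1], 0.0, max(y[0], 0.0))
            resid = y - model_response(x, params)
            return BindingFitResult(
                model=self,
                params=params,
                bse=dict(zip(_PARAM_NAMES, [0.0, np.nan, 0.0, 0.0])),
                rss=float(resid @ resid),
                converged=True,
                n_iter=0,
                kd_unidentifiable=True,
            )

        if start is None:
            theta0 = self._initial_guess()
        elif isinstance(start, BindingModelParams):
            theta0 = start.as_array()
        else:
            theta0 = np.asarray(start, float)
        lower = np.array([0.0, 1e-9, 0.0, 0.0])
        theta0 = np.maximum(theta0, lower + 1e-12)

        def resid(theta):
            bmax, kd, ns, bg = theta
            return w * (bmax * x / (x + kd) + ns * x + bg - y)

        sol = least_squares(
            resid,
            theta0,
            bounds=(lower, np.inf),
            xtol=xtol,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=max_iter,
        )
        bmax, kd, ns, bg = sol.x
        params = BindingModelParams(bmax, max(kd, 1e-9), ns, bg)
        bse = self._standard_errors(sol, len(y))
        kd_flag = bool(bmax < 1e-8 * max(abs(y).max(), 1.0) or not np.isfinite(bse["Kd"]))
        return BindingFitResult(
            model=self,
            params=params,
            bse=bse,
            rss=float(sol.fun @ sol.fun),
            converged=bool(sol.status > 0),
            n_iter=int(sol.nfev),
            kd_unidentifiable=kd_flag,
        )

    @staticmethod
    def _standard_errors(sol, n_obs: int) -> dict[str, float]:
        """Asymptotic SEs from the Jacobian at the optimum."""
        dof = max(n_obs - sol.x.size, 1)
        s2 = float(sol.fun @ sol.fun) / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(sol.x.size, np.nan)
        return dict(zip(_PARAM_NAMES, (float(v) for v in se)))


@dataclass
class BindingFitResult:
    """Estimates, uncertainties and diagnostics of a saturation-binding fit."""

    model: SaturationBindingModel
    params: BindingModelParams
    bse: dict[str, float]
    rss: float
    converged: bool
    n_iter: int
    kd_unidentifiable: bool = False

    @property
    def kd(self) -> float:
        return self.params.Kd

    @property
    def kd_se(self) -> float:
        return self.bse["Kd"]

    def predict(self, X=None):
        return self.model.predict(self.params, X)

    def fitted_curve(self) -> pd.DataFrame:
        """The fitted response sampled at the input doses."""
        doses = np.sort(self.model.fit_data["dose_nM"].unique())
        return pd.DataFrame(
            {"dose_nM": doses, "fitted_response": model_response(doses, self.params)}
        )

    def summary(self) -> str:
        lines = [
            "Saturation binding fit (Bmax*X/(X+Kd) + NS*X + Background)",
            f"  n obs: {len(self.model.fit_data)}   RSS: {self.rss:.6g}   "
            f"converged: {self.converged}   evals: {self.n_iter}",
        ]
        units = {"Bmax": "units", "Kd": "nM", "NS": "units/nM", "Background": "units"}
        values = dict(zip(_PARAM_NAMES, self.params.as_array()))
        for name in _PARAM_NAMES:
            lines.append(
                f"  {name:<10s} {values[name]:>12.4g} +/- {self.bse[name]:<10.3g} {units[name]}"
            )
        if self.kd_unidentifiable:
            lines.append("  warning: Kd unidentifiable (flat or zero-signal data)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curve on linear axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.fit_data
        ax.scatter(d["dose_nM"], d["response"], s=18, label="observed")
        xs = np.linspace(0, float(d["dose_nM"].max()) * 1.05, 200)
        ax.plot(xs, model_response(xs, self.params), label="fit")
        ax.set_xlabel("aptamer concentration (nM)")
        ax.set_ylabel("response (MFI units)")
        ax.legend()
        return ax


def fit_kd(data: pd.DataFrame, **kw) -> BindingFitResult:
    """Convenience wrapper: fit the saturation model to a dose-response table."""
    return SaturationBindingModel(data).fit(**kw)


def pool_kd(results: Sequence[BindingFitResult]) -> pd.DataFrame:
    """Pooled summary over independent replicate fits.

    One row per fit (Kd and its asymptotic SE) plus a ``pooled`` row giving
    mean +/- SD of Kd across fits — the convention in which a per-aptamer
    affinity is typically quoted (e.g. ``139 +/- 14 nM``).  Both the
    between-fit SD and the within-fit SEs are reported, labelled.
    """
    rows = [
        {"fit": i, "Kd_nM": r.kd, "Kd_se_nM": r.kd_se, "converged": r.converged}
        for i, r in enumerate(results)
    ]
    df = pd.DataFrame(rows)
    kds = df["Kd_nM"].to_numpy(float)
    pooled = {
        "fit": "pooled",
        "Kd_nM": float(kds.mean()),
        "Kd_se_nM": float(kds.std(ddof=1)) if len(kds) > 1 else np.nan,
        "converged": bool(df["converged"].all()),
    }
    if len(kds) <= 1:
        warnings.warn("pooled SD undefined with a single fit", stacklevel=2)
    return pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)
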