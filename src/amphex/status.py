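"""Multinomial logistic regression of Red List status change on exposure.

The outcome of a reassessment period is one of ``no_change`` (reference),
``uplisted`` (status deterioration) or ``downlisted`` (improvement); the
predictors are the three exposure proportions (heat wave, drought, cold
spell), each continuous in [0, 1].  With reference category fixed at linear
predictor 0, the probability of outcome k for covariate row x is

    P(y = k | x) = exp(x' b_k) / (1 + sum_j exp(x' b_j))

and exp(b) is the multiplicative change in the odds of outcome k versus no
change as a predictor moves from 0 to 1 (an odds ratio).  Estimation is
Newton-Raphson on the multinomial log-likelihood with step-halving;
uncertainties are Wald, from the observed information at the optimum.

The API follows the Model/Results convention: build a
:class:`StatusChangeModel` from data, call :meth:`~StatusChangeModel.fit`,
and read estimates off the returned :class:`StatusChangeResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PREDICTORS = ("heat_exposure", "drought_exposure", "cold_exposure")
OUTCOME_LEVELS = ("no_change", "uplisted", "downlisted")

_SEPARATION_COEF = 15.0  # |coefficient| beyond which separation is suspected


class ConvergenceError(RuntimeError):
    pass


class StatusChangeModel:
    """Multinomial logit of a categorical outcome against exposure predictors.

    Parameters
    ----------
    endog
        Outcome labels, length n.
    exog
        Design matrix (n, p) *without* intercept; one is prepended.
    reference
        Outcome level whose linear predictor is fixed at zero.
    """

    def __init__(
        self,
        endog,
        exog,
        reference: str = "no_change",
        exog_names: list[str] | None = None,
        outcome_levels: list[str] | None = None,
    ) -> None:
        endog = np.asarray(endog)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if len(endog) != exog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if not np.all(np.isfinite(exog)):
            raise ValueError("missing or non-finite predictor values")
        levels = list(outcome_levels) if outcome_levels else sorted(set(map(str, endog)))
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from outcomes")
        present = set(map(str, endog))
        levels = [l for l in levels if l in present or l == reference]
        if len(levels) < 2:
            raise ValueError("need at least two outcome levels")
        if len(levels) == 2:
            warnings.warn(
                "only two outcome levels present; model degrades to a binary logit",
                stacklevel=2,
            )
        self.reference = reference
        self.alternatives = [l for l in levels if l != reference]
        self.outcome_levels = [reference] + self.alternatives
        code = {l: k for k, l in enumerate(self.outcome_levels)}
        self._y = np.array([code[str(v)] for v in endog])
        self.exog = np.column_stack([np.ones(exog.shape[0]), exog])
        self.exog_names = ["(Intercept)"] + list(
            exog_names or [f"x{i + 1}" for i in range(exog.shape[1])]
        )
        # indicator matrix (n, K-1) for the non-reference outcomes
        self._ind = np.equal.outer(self._y, np.arange(1, len(self.outcome_levels)))
        self._ind = self._ind.astype(float)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "outcome",
        predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
        reference: str = "no_change",
    ) -> "StatusChangeModel":
        missing = [c for c in (outcome, *predictors) if c not in data.columns]
        if missing:
            raise KeyError(f"columns missing from data: {missing}")
        if data[list(predictors)].isna().any().any():
            raise ValueError("missing predictor values")
        return cls(
            data[outcome].to_numpy(),
            data[list(predictors)].to_numpy(),
            reference=reference,
            exog_names=list(predictors),
            outcome_levels=[reference]
            + [l for l in OUTCOME_LEVELS if l != reference]
            + sorted(set(map(str, data[outcome])) - set(OUTCOME_LEVELS)),
        )

    # -- likelihood machinery -------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    @property
    def k_params(self) -> int:
        return len(self.alternatives) * self.exog.shape[1]

    def _eta(self, params: np.ndarray) -> np.ndarray:
        b = params.reshape(len(self.alternatives), self.exog.shape[1])
        return self.exog @ b.T  # (n, K-1)

    def predict(self, params: np.ndarray, exog: np.ndarray | None = None) -> np.ndarray:
        """Outcome probabilities, columns ordered as ``outcome_levels``."""
        if exog is None:
            X = self.exog
        else:
            exog = np.asarray(exog, dtype=float)
            if exog.ndim == 1:
                exog = exog[None, :]
            X = np.column_stack([np.ones(exog.shape[0]), exog])
        b = np.asarray(params, dtype=float).reshape(
            len(self.alternatives), self.exog.shape[1]
        )
        eta = np.column_stack([np.zeros(X.shape[0]), X @ b.T])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def loglike(self, params: np.ndarray) -> float:
        eta = self._eta(params)
        m = np.maximum(eta.max(axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        return float((self._ind * eta).sum() - lse.sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        p = self.predict(params)[:, 1:]
        return (self.exog.T @ (self._ind - p)).T.ravel()

    def hessian(self, params: np.ndarray) -> np.ndarray:
        """Observed information times -1 (the Hessian of the log-likelihood)."""
        p = self.predict(params)[:, 1:]
        K1 = len(self.alternatives)
        q = self.exog.shape[1]
        H = np.empty((K1 * q, K1 * q))
        for k in range(K1):
            for l in range(k, K1):
                w = p[:, k] * ((k == l) - p[:, l])
                block = -(self.exog * w[:, None]).T @ self.exog
                H[k * q : (k + 1) * q, l * q : (l + 1) * q] = block
                H[l * q : (l + 1) * q, k * q : (k + 1) * q] = block.T
        return H

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 200,
        gtol: float = 1e-8,
    ) -> "StatusChangeResults":
        """Maximize the log-likelihood by Newton iterations with step-halving.

        Convergence requires a gradient max-norm below ``gtol``; failure to
        converge within ``maxiter`` iterations raises :class:`ConvergenceError`.
        """
        params = (
            np.zeros(self.k_params)
            if start_params is None
            else np.asarray(start_params, dtype=float).copy()
        )
        ll = self.loglike(params)
        ll_path = [ll]
        converged = False
        for _ in range(maxiter):
            g = self.score(params)
            if np.max(np.abs(g)) < gtol:
                converged = True
                break
            H = self.hessian(params)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, -g, rcond=None)[0]
            scale = 1.0
            for _ in range(50):
                cand = params + scale * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            params = params + scale * step
            ll = self.loglike(params)
            ll_path.append(ll)
        else:
            g = self.score(params)
            converged = np.max(np.abs(g)) < gtol
        if not converged:
            raise ConvergenceError(
                f"Newton iterations did not converge within {maxiter} steps "
                f"(gradient max-norm {np.max(np.abs(self.score(params))):.3g})"
            )
        cov = np.linalg.inv(-self.hessian(params))
        separation = bool(np.max(np.abs(params)) > _SEPARATION_COEF)
        if separation:
            warnings.warn(
                "very large coefficients suggest (quasi-)separation; "
                "Wald intervals are unreliable",
                stacklevel=2,
            )
        return StatusChangeResults(
            model=self,
            params=params,
            cov_params=cov,
            llf=ll,
            ll_path=np.array(ll_path),
            converged=True,
            separation_suspected=separation,
        )


@dataclass
class StatusChangeResults:
    """Fitted multinomial logit: estimates, Wald uncertainty, diagnostics."""

    model: StatusChangeModel
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    ll_path: np.ndarray
    converged: bool
    separation_suspected: bool

    def _index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [self.model.alternatives, self.model.exog_names],
            names=["outcome", "predictor"],
        )

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params, index=self._index(), name="coef")

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params))
        return pd.Series(se, index=self._index(), name="se")

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("odds_ratio")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse.to_numpy())
        hi = np.exp(self.params + z * self.bse.to_numpy())
        return pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=self._index())

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse.to_numpy()
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.Series(p, index=self._index(), name="p")

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict_probabilities(self, exog=None) -> pd.DataFrame:
        """Per-outcome probabilities (softmax; rows sum to one)."""
        if isinstance(exog, pd.DataFrame):
            exog = exog[self.model.exog_names[1:]].to_numpy()
        p = self.model.predict(self.params, exog)
        return pd.DataFrame(p, columns=self.model.outcome_levels)

    def summary_frame(self) -> pd.DataFrame:
        """Odds ratios with 95% Wald intervals and p-values, one row per term."""
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "odds_ratio": self.odds_ratios,
                "ci_low": ci["ci_low"],
                "ci_high": ci["ci_high"],
                "p": self.pvalues,
            }
        )
        return out.reset_index()

    def summary(self) -> str:
        sf = self.summary_frame()
        lines = [
            "Multinomial logit of status change "
            f"(reference: {self.model.reference}, n = {self.nobs})",
            f"log-likelihood = {self.llf:.3f}; converged = {self.converged}",
        ]
        if self.separation_suspected:
            lines.append("WARNING: separation suspected; intervals unreliable")
        with pd.option_context("display.float_format", "{:0.3g}".format):
            lines.append(sf.to_string(index=False))
        return "\n".join(lines)


def fit_multinomial(
    records: pd.DataFrame,
    reference: str = "no_change",
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> StatusChangeResults:
    """Fit the status-change model from a tidy records table."""
    return StatusChangeModel.from_dataframe(
        records, predictors=predictors, reference=reference
    ).fit()


def predict_probabilities(fit: StatusChangeResults, predictors) -> pd.DataFrame:
    """Outcome probabilities for new predictor rows (module-level convenience)."""
    return fit.predict_probabilities(predictors)
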