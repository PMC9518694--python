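"""Bayesian logistic regression of incident cognitive impairment on fluency scores.

The modelling core follows the Model/Results convention: a
:class:`BayesLogit` model is built from an outcome vector and a design
matrix (usually via :func:`build_design`, which encodes demographics and
residualizes each novel fluency score on the raw score so its coefficient
is not inflated by that shared variance).  ``fit()`` computes the posterior
by quadratic (Laplace) approximation — every coefficient carries an
uninformative N(0, 100^2) prior — and ``fit_mcmc()`` by adaptive
random-walk Metropolis.  Both return a :class:`BayesLogitResults` carrying
posterior draws, the pointwise log-likelihood matrix, WAIC, 97% highest
density intervals, and a ``summary()`` table.

Model comparison utilities: WAIC and Akaike-type model weights,
classification metrics (AUC, sensitivity, specificity, PPV, NPV, F1) from
posterior-mean event probabilities, and the net reclassification
improvement (NRI) of one model over another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .agreement import residualize

logger = logging.getLogger(__name__)

EDUCATION_LEVELS = ("less_than_hs", "hs", "some_college", "college_grad")
REGIONS = ("nonbelt", "belt", "buckle")


@dataclass
class ModelDesign:
    """Outcome vector and named design matrix (intercept included)."""

    y: np.ndarray
    X: pd.DataFrame

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != len(self.X):
            raise ValueError("outcome and design are not aligned")
        if np.isnan(self.X.to_numpy()).any() or np.isnan(self.y).any():
            raise ValueError("design contains missing values")


def encode_demographics(demo: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code demographic covariates with documented reference levels.

    age -> numeric; sex -> ``male`` (reference female); education (4 levels)
    -> ``hs``, ``some_college``, ``college_grad`` (reference less than high
    school); race -> ``white`` (reference black); region -> ``belt``,
    ``buckle`` (reference nonbelt).
    """
    out = pd.DataFrame(index=demo.index)
    out["age"] = demo["age"].astype(float)
    out["male"] = (demo["sex"].str.lower() == "male").astype(float)
    edu = demo["education"].str.lower()
    unknown = set(edu.unique()) - set(EDUCATION_LEVELS)
    if unknown:
        raise ValueError(f"unknown education level(s): {sorted(unknown)}")
    for level in EDUCATION_LEVELS[1:]:
        out[level] = (edu == level).astype(float)
    out["white"] = (demo["race"].str.lower() == "white").astype(float)
    region = demo["region"].str.lower()
    for level in REGIONS[1:]:
        out[level] = (region == level).astype(float)
    return out


def build_design(
    outcome: Sequence[int],
    demographics: pd.DataFrame,
    scores: pd.DataFrame,
    novel: Sequence[str] = (),
) -> ModelDesign:
    """Assemble the regression design for one model specification.

    The base predictors are the encoded demographics plus ``raw``,
    ``repetitions`` and ``intrusions`` from ``scores``.  Each column named
    in ``novel`` is added as the residual after regressing it on the raw
    score, making it orthogonal to raw by construction.  Rows with missing
    demographics are dropped with a warning.
    """
    demo = demographics.copy()
    complete = demo.notna().all(axis=1)
    if not complete.all():
        logger.warning("dropping %d rows with missing demographics", int((~complete).sum()))
    demo = demo.loc[complete]
    scores = scores.loc[demo.index]
    y = np.asarray(outcome, dtype=float)[complete.to_numpy()]
    X = encode_demographics(demo)
    for col in ("raw", "repetitions", "intrusions"):
        X[col] = scores[col].astype(float)
    raw = scores["raw"].to_numpy(dtype=float)
    for col in novel:
        X[col] = residualize(scores[col].to_numpy(dtype=float), raw)
    X.insert(0, "const", 1.0)
    return ModelDesign(y, X)


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


class BayesLogit:
    """Bayesian logistic regression with independent N(0, prior_sd^2) priors."""

    def __init__(self, endog: Sequence[float], exog: pd.DataFrame | np.ndarray,
                 prior_sd: float = 100.0):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog are not aligned")
        self.prior_sd = float(prior_sd)
        self._check_rank()

    @classmethod
    def from_design(cls, design: ModelDesign, prior_sd: float = 100.0) -> "BayesLogit":
        return cls(design.y, design.X, prior_sd=prior_sd)

    def _check_rank(self) -> None:
        x = self.exog
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            _, r = np.linalg.qr(x)
            bad = [self.exog_names[i] for i in range(x.shape[1])
                   if abs(r[i, i]) < 1e-8 * max(abs(np.diag(r)))]
            raise ValueError(f"design is rank deficient; collinear column(s): {bad}")

    def logpost(self, beta: np.ndarray) -> float:
        z = self.exog @ beta
        ll = float(np.sum(self.endog * _log_sigmoid(z) + (1 - self.endog) * _log_sigmoid(-z)))
        return ll - float(np.sum(beta**2)) / (2 * self.prior_sd**2)

    def _mode_and_cov(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode by damped Newton iterations; covariance from the Hessian."""
        x, y, s2 = self.exog, self.endog, self.prior_sd**2
        beta = np.zeros(x.shape[1])
        lp = self.logpost(beta)
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-(x @ beta)))
            grad = x.T @ (y - p) - beta / s2
            w = p * (1.0 - p)
            hess = -(x.T * w) @ x - np.eye(x.shape[1]) / s2
            step = np.linalg.solve(-hess, grad)
            scale = 1.0
            while scale > 1e-8:
                cand = beta + scale * step
                lp_cand = self.logpost(cand)
                if lp_cand >= lp - 1e-12:
                    break
                scale /= 2.0
            beta, lp = beta + scale * step, self.logpost(beta + scale * step)
            if np.max(np.abs(grad)) < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(x @ beta)))
        w = p * (1.0 - p)
        hess = -(x.T * w) @ x - np.eye(x.shape[1]) / s2
        cov = np.linalg.inv(-hess)
        if np.any(np.abs(beta) > 20):
            logger.warning("large posterior mode coefficient(s) (|b| > 20); possible separation")
        return beta, cov

    def fit(self, draws: int = 2000, seed: int = 0) -> "BayesLogitResults":
        """Quadratic (Laplace) approximation: normal posterior at the mode."""
        mode, cov = self._mode_and_cov()
        rng = np.random.default_rng(seed)
        samples = rng.multivariate_normal(mode, cov, size=draws, method="cholesky")
        return BayesLogitResults(self, mode, cov, samples[None, :, :], method="laplace")

    def fit_mcmc(self, draws: int = 2000, chains: int = 2, warmup: int = 1000,
                 seed: int = 0) -> "BayesLogitResults":
        """Adaptive random-walk Metropolis started and scaled from the Laplace fit.

        The proposal covariance is the Laplace covariance times the usual
        2.38^2 / d factor, rescaled during warmup toward ~25% acceptance.
        Deterministic given ``seed``.
        """
        mode, cov = self._mode_and_cov()
        d = len(mode)
        chol = np.linalg.cholesky(cov * (2.38**2 / d))
        all_chains = np.empty((chains, draws, d))
        for c in range(chains):
            rng = np.random.default_rng([seed, c])
            beta = mode + 0.1 * (chol @ rng.standard_normal(d))
            lp = self.logpost(beta)
            scale, accepted = 1.0, 0
            for it in range(warmup + draws):
                prop = beta + scale * (chol @ rng.standard_normal(d))
                lp_prop = self.logpost(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    beta, lp = prop, lp_prop
                    accepted += 1
                if it < warmup:
                    if (it + 1) % 100 == 0:
                        rate = accepted / (it + 1)
                        scale *= np.exp(rate - 0.25)
                else:
                    all_chains[c, it - warmup] = beta
        res = BayesLogitResults(self, mode, cov, all_chains, method="mcmc")
        low = res.ess()[res.ess() < 100]
        if len(low):
            logger.warning("effective sample size < 100 for %s; consider more draws",
                           list(low.index))
        return res


class BayesLogitResults:
    """Posterior fit: draws, WAIC, HDIs, predictions, and a summary table."""

    def __init__(self, model: BayesLogit, mode: np.ndarray, cov: np.ndarray,
                 chains: np.ndarray, method: str):
        self.model = model
        self.mode = mode
        self.cov = cov
        self.chains = chains  # (chain, draw, dim)
        self.method = method
        self.names = model.exog_names

    @property
    def draws(self) -> np.ndarray:
        """All posterior draws pooled across chains, shape (S, dim)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=self.names)

    def pointwise_loglik(self) -> np.ndarray:
        """Log-likelihood of each observation under each draw, shape (n, S)."""
        z = self.model.exog @ self.draws.T
        y = self.model.endog[:, None]
        return y * _log_sigmoid(z) + (1 - y) * _log_sigmoid(-z)

    @property
    def waic(self) -> float:
        return waic(self.pointwise_loglik())

    def hdi(self, prob: float = 0.97) -> pd.DataFrame:
        bounds = az.hdi(self.chains, hdi_prob=prob)
        return pd.DataFrame(bounds, index=self.names, columns=["hdi_low", "hdi_high"])

    def ess(self) -> pd.Series:
        vals = [float(az.ess(self.chains[:, :, i])) for i in range(len(self.names))]
        return pd.Series(vals, index=self.names)

    def predict(self, exog: np.ndarray | pd.DataFrame | None = None) -> np.ndarray:
        """Posterior predictive mean event probability per observation."""
        x = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        probs = 1.0 / (1.0 + np.exp(-(x @ self.draws.T)))
        return probs.mean(axis=1)

    def summary(self, hdi_prob: float = 0.97) -> pd.DataFrame:
        """Posterior mean, SD, and HDI per coefficient."""
        table = pd.DataFrame(
            {
                "mean": self.draws.mean(axis=0),
                "sd": self.draws.std(axis=0, ddof=1),
            },
            index=self.names,
        )
        return table.join(self.hdi(hdi_prob))


# ---------------------------------------------------------------------------
# model comparison

def waic(pointwise_loglik: np.ndarray) -> float:
    """Watanabe-Akaike information criterion from an (observations x draws) matrix.

    WAIC = -2 (lppd - p_waic) with lppd = sum_i log mean_s p(y_i | theta_s)
    and effective parameter count p_waic = sum_i var_s log p(y_i | theta_s).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if not np.all(np.isfinite(ll)):
        bad = np.argwhere(~np.isfinite(ll))[0]
        raise ValueError(f"non-finite log-likelihood at observation {int(bad[0])}")
    if ll.shape[1] < 2:
        raise ValueError("need >= 2 posterior draws")
    lppd = float(np.sum(np.logaddexp.reduce(ll, axis=1) - np.log(ll.shape[1])))
    p_waic = float(np.sum(np.var(ll, axis=1, ddof=1)))
    return -2.0 * (lppd - p_waic)


def model_weights(waics: Sequence[float]) -> np.ndarray:
    """Akaike-type weights: w_j = exp(-delta_j / 2) / sum_k exp(-delta_k / 2)."""
    w = np.asarray(waics, dtype=float)
    delta = w - w.min()
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


def classification_metrics(probs: Sequence[float], y: Sequence[int],
                           threshold: float = 0.5) -> dict[str, float]:
    """AUC (rank statistic with midrank ties) and confusion metrics at a cut."""
    p = np.asarray(probs, dtype=float)
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("AUC undefined: outcomes contain a single class")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (yv == 1)))
    tn = int(np.sum((pred == 0) & (yv == 0)))
    fp = int(np.sum((pred == 1) & (yv == 0)))
    fn = int(np.sum((pred == 0) & (yv == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) else float("nan")
    return {
        "AUC": float(roc_auc_score(yv, p)),
        "sensitivity": sens,
        "specificity": spec,
        "PPV": ppv,
        "NPV": npv,
        "F1": f1,
    }


def nri(p_base: Sequence[float], p_new: Sequence[float], y: Sequence[int],
        variant: str = "continuous", threshold: float = 0.5) -> float:
    """Net reclassification improvement of a new risk model over a base model.

    Continuous (category-free) variant: net proportion of events whose
    predicted risk moves up plus non-events whose risk moves down.
    Threshold variant: the same on crossings of a single risk cut.
    """
    pb = np.asarray(p_base, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    yv = np.asarray(y, dtype=int)
    if not (np.any(yv == 1) and np.any(yv == 0)):
        raise ValueError("NRI requires both events and non-events")
    if variant == "continuous":
        up = pn > pb
        down = pn < pb
    elif variant == "threshold":
        up = (pn >= threshold) & (pb < threshold)
        down = (pn < threshold) & (pb >= threshold)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    ev, ne = yv == 1, yv == 0
    return float(
        (up[ev].mean() - down[ev].mean()) + (down[ne].mean() - up[ne].mean())
    )


def compare_models(
    fits: Mapping[str, BayesLogitResults],
    base: str,
    threshold: float = 0.5,
    nri_variant: str = "continuous",
) -> pd.DataFrame:
    """Comparison table: WAIC, weight, AUC, Sens, Spec, NPV, PPV, F1, NRI vs base."""
    names = list(fits)
    waics = [fits[n].waic for n in names]
    weights = model_weights(waics)
    p_base = fits[base].predict()
    rows = []
    for name, w, wt in zip(names, waics, weights):
        res = fits[name]
        probs = res.predict()
        metrics = classification_metrics(probs, res.model.endog, threshold)
        row = {"model": name, "WAIC": w, "weight": float(wt), "AUC": metrics["AUC"],
               "Sens": metrics["sensitivity"], "Spec": metrics["specificity"],
               "NPV": metrics["NPV"], "PPV": metrics["PPV"], "F1": metrics["F1"]}
        row["NRI"] = (float("nan") if name == base
                      else nri(p_base, probs, res.model.endog, nri_variant, threshold))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
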