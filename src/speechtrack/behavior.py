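"""Word-by-word comprehension scoring and the logistic mixed model.

Repetition responses are scored word-by-word by longest-common-
subsequence alignment against the target sentence. Word accuracy is
then modelled with a logistic mixed model: fixed effects for word
audibility, word surprisal and their interaction, the T/D condition,
lexical/positional controls, subject-level controls (control-condition
accuracy, SRT) and the eight standardized trial-wise encoding-model
fits, with crossed random intercepts for subjects and sentences.
Estimation is Laplace/MAP with weak priors (a Bayesian-posterior-mean
engine for crossed random effects); the contract is the model, not the
engine.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "FULL_MODEL_TERMS",
    "normalize_token",
    "score_words",
    "ComprehensionModel",
    "ComprehensionResults",
    "fit_glmm",
    "vif",
]

#: fixed-effect terms of the full comprehension model (interaction
#: entered as its own term)
FULL_MODEL_TERMS = [
    "audibility",
    "surprisal",
    "audibility:surprisal",
    "fit_acoustic_target",
    "fit_onsets_target",
    "fit_word_linguistic_target",
    "fit_phoneme_linguistic_target",
    "fit_acoustic_distractor",
    "fit_onsets_distractor",
    "fit_word_linguistic_distractor",
    "fit_phoneme_linguistic_distractor",
    "td_condition",
    "word_frequency",
    "word_order",
    "sentence_length",
    "control_accuracy",
    "srt",
]


def normalize_token(token: str) -> str:
    """NFC-normalize, casefold, and strip punctuation."""
    token = unicodedata.normalize("NFC", token).casefold()
    return re.sub(r"[^\w]", "", token, flags=re.UNICODE)


def score_words(response_tokens: list[str], target_tokens: list[str]) -> np.ndarray:
    """Per-target-word accuracy by LCS alignment.

    Target words lying on a longest common subsequence of the
    normalized response and target are marked correct (1), the rest
    incorrect (0). Matching is exact on normalized tokens; no
    morphological fuzziness is applied.
    """
    if not target_tokens:
        raise ValueError("empty target sentence")
    tgt = [normalize_token(t) for t in target_tokens]
    rsp = [normalize_token(t) for t in response_tokens]
    n, m = len(tgt), len(rsp)
    L = np.zeros((n + 1, m + 1), int)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            L[i, j] = (
                L[i + 1, j + 1] + 1 if tgt[i] == rsp[j] else max(L[i + 1, j], L[i, j + 1])
            )
    acc = np.zeros(n, int)
    i = j = 0
    while i < n and j < m:
        if tgt[i] == rsp[j]:
            acc[i] = 1
            i += 1
            j += 1
        elif L[i + 1, j] >= L[i, j + 1]:
            i += 1
        else:
            j += 1
    return acc


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


class ComprehensionModel:
    """Logistic mixed model for word-level comprehension accuracy.

    Parameters
    ----------
    table
        One row per scored word with an ``accuracy`` column in {0, 1},
        the fixed-effect predictor columns, and the grouping columns.
    fixed_terms
        Fixed effects; ``a:b`` denotes an interaction column computed
        as the product of the (standardized) main effects.
    groups
        Columns defining the two crossed random intercepts
        (default subject and sentence).
    standardize
        Z-score all fixed-effect predictors (the published estimates
        are on the standardized scale).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        fixed_terms: list[str] | None = None,
        groups: tuple[str, str] = ("subject", "sentence_id"),
        outcome: str = "accuracy",
        standardize: bool = True,
    ):
        self.table = table.reset_index(drop=True)
        self.groups = groups
        self.outcome = outcome
        if fixed_terms is None:
            fixed_terms = [t for t in FULL_MODEL_TERMS if self._term_available(t)]
        self.fixed_terms = list(fixed_terms)
        for g in groups:
            if self.table[g].nunique() < 2:
                raise ValueError(f"need >= 2 levels of {g!r}")
        cols = {}
        for term in self.fixed_terms:
            x = self._term_column(term)
            cols[term] = _standardize(x) if standardize else x
        # interactions are products of the standardized mains
        for term in self.fixed_terms:
            if ":" in term:
                a, b = term.split(":")
                cols[term] = cols[a] * cols[b] if a in cols and b in cols else (
                    _standardize(self._term_column(a)) * _standardize(self._term_column(b))
                )
        self.X = np.column_stack([np.ones(len(self.table))] + [cols[t] for t in self.fixed_terms])
        self.exog_names = ["intercept"] + self.fixed_terms
        self._cols = cols
        self.y = self.table[outcome].to_numpy(float)

    def _term_available(self, term: str) -> bool:
        if ":" in term:
            return all(p in self.table.columns for p in term.split(":"))
        return term in self.table.columns

    def _term_column(self, term: str) -> np.ndarray:
        if ":" in term:
            a, b = term.split(":")
            return self.table[a].to_numpy(float) * self.table[b].to_numpy(float)
        return self.table[term].to_numpy(float)

    def _vc_matrices(self):
        n = len(self.table)
        mats, idents, names = [], [], []
        for k, g in enumerate(self.groups):
            codes, _ = pd.factorize(self.table[g])
            Z = sp.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, codes.max() + 1)
            )
            mats.append(Z)
            idents.append(np.full(Z.shape[1], k))
            names.append(g)
        return sp.hstack(mats).tocsr(), np.concatenate(idents), names

    def fit(self, fe_prior_sd: float = 3.0, vcp_prior_sd: float = 2.0) -> "ComprehensionResults":
        """Fit by Laplace/MAP with weak Gaussian priors.

        When a random-intercept variance sits on the zero boundary
        (common for very small group counts) the log-scale gradient
        cannot vanish; the fit is retried with a progressively tighter
        variance prior and the boundary is reported in a warning.
        A diagnostic error with the gradient norm is raised if no
        attempt yields finite estimates.
        """
        exog_vc, ident, vc_names = self._vc_matrices()
        last_grad = np.inf
        for k, vcp in enumerate([vcp_prior_sd, 1.0, 0.5]):
            glmm = BinomialBayesMixedGLM(
                self.y, self.X, exog_vc, ident, vcp_p=vcp, fe_p=fe_prior_sd
            )
            with warnings.catch_warnings(record=True) as rec:
                warnings.simplefilter("always")
                res = glmm.fit_map()
            conv = [w for w in rec if "did not converge" in str(w.message)]
            finite = np.all(np.isfinite(res.fe_mean)) and np.all(np.isfinite(res.fe_sd))
            if finite and not conv:
                if k > 0:
                    warnings.warn(
                        "random-intercept variance near the boundary; "
                        f"refitted with variance prior sd={vcp}",
                        stacklevel=2,
                    )
                return ComprehensionResults(self, res, vc_names)
            if conv:
                msg = str(conv[-1].message)
                try:
                    last_grad = float(msg.rsplit("=", 1)[1])
                except (IndexError, ValueError):
                    last_grad = np.nan
                if finite and last_grad < 1e-2:
                    # converged to numerical tolerance; accept quietly
                    return ComprehensionResults(self, res, vc_names)
        if np.all(np.isfinite(res.fe_mean)):
            warnings.warn(
                "GLMM optimizer stopped at a boundary "
                f"(|gradient|={last_grad:.3g}); estimates may be unstable",
                stacklevel=2,
            )
            return ComprehensionResults(self, res, vc_names)
        raise RuntimeError(f"GLMM did not converge (|gradient|={last_grad:.3g})")


@dataclass
class ComprehensionResults:
    """Estimates, uncertainties, diagnostics and summaries of the fit."""

    model: ComprehensionModel
    _res: object = field(repr=False)
    vc_names: list[str] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.fe_mean, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.fe_sd, index=self.model.exog_names)

    @property
    def re_sd(self) -> pd.Series:
        """Random-intercept SDs (posterior means on the log-sd scale)."""
        return pd.Series(np.exp(self._res.vcp_mean), index=self.vc_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def coef_table(self) -> pd.DataFrame:
        """Per-term estimate, SE, CI, z, raw and BH-FDR p-values.

        FDR correction spans the fixed-effect terms (the intercept is
        not a hypothesis and is left uncorrected).
        """
        est, se = self.params, self.bse
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        ci = self.conf_int()
        tbl = pd.DataFrame(
            {
                "estimate": est,
                "std_error": se,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "z": z,
                "p": p,
            }
        )
        mask = np.asarray(tbl.index != "intercept")
        fdr = np.full(len(tbl), np.nan)
        fdr[mask.nonzero()[0]] = stats.false_discovery_control(
            tbl.loc[mask, "p"], method="bh"
        )
        tbl["p_fdr"] = fdr
        return tbl

    def variance_explained(self) -> tuple[float, float]:
        """Latent-scale pseudo-R^2 (fixed-only, total).

        fixed = var(X beta) / (var(X beta) + sum sigma^2_re + pi^2/3);
        total adds the random-intercept variances to the numerator.
        """
        xb = self.model.X @ self._res.fe_mean
        var_f = float(np.var(xb))
        var_re = float((self.re_sd**2).sum())
        denom = var_f + var_re + np.pi**2 / 3
        return var_f / denom, (var_f + var_re) / denom

    def vif(self) -> pd.Series:
        return vif(self.model)

    def summary(self) -> str:
        tbl = self.coef_table()
        fixed, total = self.variance_explained()
        lines = [
            "Logistic mixed model: word comprehension accuracy",
            f"  rows: {len(self.model.table)}   "
            f"groups: {', '.join(f'{g} ({self.model.table[g].nunique()})' for g in self.model.groups)}",
            f"  random-intercept SDs: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.re_sd.items()),
            f"  variance explained: fixed-only {100*fixed:.1f}%, total {100*total:.1f}%",
            "",
            tbl.round(4).to_string(),
        ]
        return "\n".join(lines)


def fit_glmm(
    table: pd.DataFrame,
    fixed_terms: list[str] | None = None,
    groups: tuple[str, str] = ("subject", "sentence_id"),
    **fit_kwargs,
) -> ComprehensionResults:
    """Functional wrapper: build the model and fit in one call."""
    return ComprehensionModel(table, fixed_terms, groups).fit(**fit_kwargs)


def vif(model: ComprehensionModel | pd.DataFrame, fixed_terms: list[str] | None = None) -> pd.Series:
    """Variance inflation factors of the fixed-effect design.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing term j on the others
    (the interaction counts as its own column). Perfect collinearity
    reports infinity with a warning.
    """
    if isinstance(model, ComprehensionModel):
        names = model.fixed_terms
        X = model.X[:, 1:]
    else:
        if fixed_terms is None or len(fixed_terms) < 2:
            raise ValueError("need at least 2 terms")
        names = list(fixed_terms)
        cols = []
        for t in names:
            if ":" in t:
                a, b = t.split(":")
                cols.append(
                    _standardize(model[a].to_numpy(float))
                    * _standardize(model[b].to_numpy(float))
                )
            else:
                cols.append(_standardize(model[t].to_numpy(float)))
        X = np.column_stack(cols)
    if len(names) < 2:
        raise ValueError("need at least 2 terms")
    R = np.corrcoef(X, rowvar=False)
    out = np.empty(len(names))
    try:
        Rinv = np.linalg.inv(R)
        out[:] = np.diag(Rinv)
        if np.any(out < 0) or not np.all(np.isfinite(out)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("perfectly collinear predictors; VIF set to inf", stacklevel=2)
        for j in range(len(names)):
            others = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(X.shape[0]), others]), X[:, j], rcond=None
            )
            resid = X[:, j] - np.column_stack([np.ones(X.shape[0]), others]) @ beta
            r2 = 1 - resid.var() / X[:, j].var()
            out[j] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names)
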