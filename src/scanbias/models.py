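"""Mixed-effects contrast analyses of bias and search-efficiency data.

The analyses here are defined by their *contrasts*: a two-level target-side
factor entered with dummy coding (reference level left or right) or simple
±0.5 coding, crossed random intercepts for subjects and scene items, and
optionally a by-item random slope for target side. Numerical optimisation
of the (G)LMMs is delegated to lme4 (`glmer`/`lmer` driven through Rscript);
this module owns the design-matrix construction, the fixed-effect table,
log-likelihood-based model comparison, and extraction of per-item
conditional modes.

p-values for Gaussian LMM fixed effects use a normal approximation of the
t statistic by default; `df_method="satterthwaite"` delegates the
degrees-of-freedom adjustment to lmerTest.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "FixedEffect",
    "ModelFit",
    "ModelComparison",
    "ConvergenceError",
    "SeparationError",
    "fit_mixed",
    "compare_models",
    "inverse_logit",
]

CODINGS = ("dummy_left_ref", "dummy_right_ref", "simple_pm_half")
FAMILIES = ("binomial_logit", "gaussian")


class ConvergenceError(RuntimeError):
    """The optimizer failed in a way that invalidates the fit."""


class SeparationError(ConvergenceError):
    """Complete separation: the binomial likelihood has no finite optimum."""


@dataclass(frozen=True)
class FixedEffect:
    term: str
    b: float
    se: float
    stat: float   # z (binomial) or t (gaussian)
    p: float


@dataclass
class ModelFit:
    family: str
    coding: Optional[str]
    formula: str
    fixed_effects: list
    fixed_vcov: np.ndarray        # covariance of the fixed effects
    random_effects: dict          # component name -> variance
    conditional_modes: dict       # grouping factor -> {level: mode, ...}
    log_likelihood: float
    n_params: int
    n_obs: int
    converged: bool = True
    singular: bool = False
    messages: list = field(default_factory=list)

    def effect(self, term: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.term == term:
                return fe
        raise KeyError(term)

    @property
    def intercept(self) -> FixedEffect:
        return self.effect("(Intercept)")

    def combination(self, weights) -> tuple[float, float]:
        """Estimate and SE of a linear combination of the fixed effects."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(self.fixed_effects),):
            raise ValueError("one weight per fixed effect required")
        b = float(w @ np.array([fe.b for fe in self.fixed_effects]))
        se = float(np.sqrt(w @ self.fixed_vcov @ w))
        return b, se

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        from dataclasses import asdict
        return {
            "family": self.family, "coding": self.coding,
            "formula": self.formula,
            "fixed_effects": [asdict(fe) for fe in self.fixed_effects],
            "random_effects": self.random_effects,
            "conditional_modes": self.conditional_modes,
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params, "n_obs": self.n_obs,
            "converged": self.converged, "singular": self.singular,
            "messages": self.messages,
        }


@dataclass(frozen=True)
class ModelComparison:
    delta_chi2: float
    df: int
    p: float


def inverse_logit(b: float) -> float:
    """logit^-1(b) = 1 / (1 + exp(-b))."""
    return float(expit(b))


def _code_side(side: pd.Series, coding: str) -> np.ndarray:
    is_right = side.astype(str).str.lower().eq("right")
    is_left = side.astype(str).str.lower().eq("left")
    if not (is_right | is_left).all():
        raise ValueError("target side column must contain only left/right")
    if coding == "dummy_left_ref":
        return is_right.to_numpy(dtype=float)
    if coding == "dummy_right_ref":
        return is_left.to_numpy(dtype=float)
    if coding == "simple_pm_half":
        return np.where(is_right, 0.5, -0.5)
    raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")


_R_TEMPLATE = """
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
{extra_libs}
d <- read.csv("{data}")
d$subject <- factor(d$subject); d$item <- factor(d$item)
fit <- {fit_call}
msgs <- unlist(fit@optinfo$conv$lme4$messages)
if (is.null(msgs)) msgs <- character(0)
s <- summary(fit)
fe <- coef(s)
vc <- as.data.frame(VarCorr(fit))
re <- ranef(fit)
res <- list(
  terms = rownames(fe),
  table = unname(as.matrix(fe)), tcols = colnames(fe),
  vcov = unname(as.matrix(vcov(fit))),
  loglik = as.numeric(logLik(fit)), npar = attr(logLik(fit), "df"),
  n = nobs(fit),
  vc_names = paste(vc$grp, ifelse(is.na(vc$var1), "", vc$var1)),
  vc_var = vc$vcov,
  singular = isSingular(fit),
  messages = msgs,
  modes = lapply(re, function(g) as.list(setNames(g[, 1], rownames(g))))
)
write(toJSON(res, digits = 12, auto_unbox = FALSE, null = "null"),
      "{out}")
"""


def _run_lme4(df: pd.DataFrame, formula: str, family: str,
              df_method: str) -> dict:
    if shutil.which("Rscript") is None:  # pragma: no cover - env guarantee
        raise RuntimeError("Rscript (with lme4) is required for mixed models")
    with tempfile.TemporaryDirectory(prefix="scanbias_lme4_") as tmp:
        data = Path(tmp) / "data.csv"
        out = Path(tmp) / "fit.json"
        script = Path(tmp) / "fit.R"
        df.to_csv(data, index=False)
        # tight optimizer tolerances so reparameterised fits agree to ~1e-6
        gctrl = ('glmerControl(tolPwrss = 1e-12, optCtrl = list('
                 'FtolAbs = 1e-14, FtolRel = 1e-15, XtolRel = 1e-14, '
                 'maxfun = 100000))')
        lctrl = ('lmerControl(optCtrl = list(FtolAbs = 1e-14, '
                 'FtolRel = 1e-15, XtolRel = 1e-14, maxfun = 100000))')
        if family == "binomial_logit":
            fit_call = (f'glmer({formula}, data = d, family = binomial, '
                        f'control = {gctrl})')
            extra = ""
        elif df_method == "satterthwaite":
            fit_call = (f'lmerTest::lmer({formula}, data = d, REML = FALSE, '
                        f'control = {lctrl})')
            extra = "suppressMessages(library(lmerTest))"
        else:
            fit_call = (f'lmer({formula}, data = d, REML = FALSE, '
                        f'control = {lctrl})')
            extra = ""
        script.write_text(_R_TEMPLATE.format(
            extra_libs=extra, data=data.as_posix(), out=out.as_posix(),
            fit_call=fit_call))
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise ConvergenceError(
                "lme4 fit failed:\n" + proc.stderr.strip()[-2000:])
        return json.loads(out.read_text())


def fit_mixed(data: pd.DataFrame, response: str,
              family: str = "binomial_logit",
              coding: Optional[str] = "dummy_left_ref",
              item_slope: bool = False,
              subject_col: str = "subject", item_col: str = "item",
              side_col: str = "target_side",
              df_method: str = "normal") -> ModelFit:
    """Fit a (G)LMM of ``response`` on the target-side contrast.

    ``coding=None`` fits the varying-intercept model with no predictors.
    Random effects are crossed by-subject and by-item intercepts, plus a
    by-item random slope for the side contrast when ``item_slope`` is true.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    cols = {response, subject_col, item_col} | ({side_col} if coding else set())
    missing = cols - set(data.columns)
    if missing:
        raise ValueError(f"data is missing column(s): {sorted(missing)}")
    d = pd.DataFrame({
        "y": data[response].to_numpy(),
        "subject": data[subject_col].astype(str).to_numpy(),
        "item": data[item_col].astype(str).to_numpy(),
    })
    if family == "binomial_logit":
        y = d["y"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            raise ValueError("binomial response must be 0/1")
        if len(np.unique(y)) < 2:
            raise SeparationError("response is constant: complete separation")
    if coding is not None:
        d["x"] = _code_side(data[side_col], coding)
        if family == "binomial_logit":
            for v in np.unique(d["x"]):
                if len(np.unique(d.loc[d["x"] == v, "y"])) < 2:
                    raise SeparationError(
                        f"complete separation: response constant at x = {v}")
        rand = "(1 | subject) + (1 + x | item)" if item_slope \
            else "(1 | subject) + (1 | item)"
        formula = f"y ~ x + {rand}"
    else:
        if item_slope:
            raise ValueError("an item slope requires a side contrast")
        formula = "y ~ 1 + (1 | subject) + (1 | item)"

    res = _run_lme4(d, formula, family, df_method)

    table = np.asarray(res["table"], dtype=float)
    tcols = list(res["tcols"])
    terms = list(res["terms"])
    fixed = []
    for i, term in enumerate(terms):
        b = float(table[i, tcols.index("Estimate")])
        se = float(table[i, tcols.index("Std. Error")])
        if "z value" in tcols:
            stat = float(table[i, tcols.index("z value")])
            p = float(table[i, tcols.index("Pr(>|z|)")])
        else:
            stat = float(table[i, tcols.index("t value")])
            if "Pr(>|t|)" in tcols:  # Satterthwaite via lmerTest
                p = float(table[i, tcols.index("Pr(>|t|)")])
            else:
                p = float(2.0 * sps.norm.sf(abs(stat)))
        if family == "binomial_logit" and abs(b) > 10 and se > 30:
            raise SeparationError(
                f"complete separation detected at term {term!r} "
                f"(b = {b:.1f}, SE = {se:.1f})")
        fixed.append(FixedEffect(term, b, se, stat, p))

    messages = [str(m) for m in res.get("messages", [])]
    converged = not any("failed to converge" in m.lower() for m in messages)
    fit = ModelFit(
        family=family, coding=coding, formula=formula,
        fixed_effects=fixed,
        fixed_vcov=np.asarray(res["vcov"], dtype=float),
        random_effects={name.strip(): float(v) for name, v in
                        zip(res["vc_names"], res["vc_var"])},
        conditional_modes={g: {k: float(v[0]) if isinstance(v, list) else float(v)
                               for k, v in levels.items()}
                           for g, levels in res["modes"].items()},
        log_likelihood=float(res["loglik"][0]),
        n_params=int(res["npar"][0]),
        n_obs=int(res["n"][0]),
        converged=converged,
        singular=bool(res["singular"][0]),
        messages=messages)
    return fit


def compare_models(fit_small: ModelFit, fit_large: ModelFit,
                   ) -> ModelComparison:
    """Likelihood-ratio comparison of two nested fits on the same data.

    A negative likelihood difference (possible with approximate optima) is
    clamped to zero with a warning message attached to neither fit.
    """
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("fits are on different numbers of observations")
    df = fit_large.n_params - fit_small.n_params
    if df <= 0:
        raise ValueError("fit_large must have more parameters than fit_small")
    delta = 2.0 * (fit_large.log_likelihood - fit_small.log_likelihood)
    if delta < 0:
        import warnings
        warnings.warn("larger model has lower log-likelihood; "
                      "delta chi-square clamped at 0", RuntimeWarning,
                      stacklevel=2)
        delta = 0.0
    p = float(sps.chi2.sf(delta, df)) if delta > 0 else 1.0
    return ModelComparison(delta_chi2=float(delta), df=int(df), p=p)
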