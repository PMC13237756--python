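"""Bayesian Gaussian linear mixed models via blocked Gibbs sampling.

The response is log alpha power; fixed effects are built from the six
features Sleep, Group, Eyes, ML, AP, IS (interactions always include all
non-redundant lower-order constituents); a participant random intercept
accommodates the within-subject correlation of the 130 rows each
participant contributes.

Model:  y = X b + Z u + e,  u_j ~ N(0, σ_u²),  e ~ N(0, σ²)
Priors: b ~ N(0, τ² I) with τ = 10 (weakly informative, intercept
included), σ², σ_u² ~ Inverse-Gamma(a0, b0), a0 = b0 = 0.001.

All full conditionals are conjugate: b is multivariate normal, each u_j
normal, the variances inverse-gamma. Posterior summaries report the
median, the central 95% credible interval, the sign posterior
probability PP = max(P(b>0), P(b<0)) and its verbal evidence stratum,
plus split-chain R-hat and Geyer-truncated effective sample size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "PosteriorDraws",
    "PosteriorSummary",
    "MODEL_FORMULAS",
    "build_design",
    "gibbs_sample",
    "diagnostics",
    "summarize",
    "evidence_stratum",
    "marginal_slopes",
    "delta_over_range",
    "posterior_predictive_check",
]

FEATURES = ("Sleep", "Group", "Eyes", "ML", "AP", "IS")

#: The model suite: fixed-effect structures by model id. "x" denotes a
#: full factorial expansion into all constituent lower-order terms.
MODEL_FORMULAS: dict[int, tuple[str, ...]] = {
    1: ("Group", "Eyes", "ML x AP x IS"),
    2: ("Sleep", "Eyes", "ML x AP x IS"),
    3: ("Sleep x Group", "Eyes", "ML x AP x IS"),
    4: ("Sleep x Group x Eyes", "ML x AP x IS"),
    5: ("Sleep x Group x ML", "Eyes", "ML x AP x IS"),
    6: ("Sleep x Group x AP", "Eyes", "ML x AP x IS"),
    7: ("Sleep x Group x IS", "Eyes", "ML x AP x IS"),
}

#: Verbal evidence strata over the sign posterior probability, percent.
EVIDENCE_STRATA = (
    (50, 50, "none"),
    (51, 74, "anecdotal"),
    (75, 90, "moderate"),
    (91, 96, "strong"),
    (97, 99, "very strong"),
    (100, 100, "extreme"),
)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure plus priors for one mixed model."""

    terms: tuple[str, ...]
    model_id: int | None = None
    prior_sd: float = 10.0  # N(0, prior_sd²) on every fixed effect
    a0: float = 0.001  # inverse-gamma shape, both variances
    b0: float = 0.001  # inverse-gamma rate

    @classmethod
    def for_model(cls, model_id: int, **kwargs) -> "ModelSpec":
        if model_id not in MODEL_FORMULAS:
            raise ValueError(f"unknown model id {model_id}; choose 1–7 or pass terms")
        return cls(terms=MODEL_FORMULAS[model_id], model_id=model_id, **kwargs)

    def expanded_terms(self) -> list[tuple[str, ...]]:
        """Interaction expansion, deduplicated, deterministic order.

        Each "A x B x C" product contributes every non-empty subset; the
        intercept is implicit and prepended as the empty tuple.
        """
        seen: dict[tuple[str, ...], None] = {(): None}
        for term in self.terms:
            factors = [f.strip() for f in term.replace("*", "x").split("x")]
            for f in factors:
                if f not in FEATURES:
                    raise ValueError(
                        f"unknown model term {f!r}; valid features: {FEATURES}"
                    )
            for r in range(1, len(factors) + 1):
                for combo in itertools.combinations(factors, r):
                    key = tuple(sorted(combo, key=FEATURES.index))
                    seen.setdefault(key, None)
        return list(seen)


def _column_name(combo: tuple[str, ...]) -> str:
    return "Intercept" if not combo else ":".join(combo)


@dataclass(frozen=True)
class DesignMatrices:
    """Response, coded fixed-effects matrix and participant index."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, p)
    columns: tuple[str, ...]
    participant_index: np.ndarray  # (n,) int codes 0..J-1
    participants: tuple[str, ...]
    feature_values: dict  # raw coded features per row, for marginal effects

    @property
    def n_participants(self) -> int:
        return len(self.participants)


#: Reference levels: group 0 = abstinent, eyes 0 = closed.
GROUP_CODES = {"abstinent": 0.0, "non_abstinent": 1.0}
EYES_CODES = {"closed": 0.0, "open": 1.0}


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Expand the model formula into a coded design matrix.

    Group is treatment-coded with abstinent as reference, eyes with
    closed as reference; Sleep enters uncentered on its 0–10 scale; the
    electrode coordinates enter as-is in [−1, 1].
    """
    if table.empty:
        raise ValueError("alpha-power table is empty")
    required = {"participant", "log_alpha_power", "group", "sleep_quality",
                "condition", "ml", "ap", "is"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    if table[list(required)].isna().any().any():
        raise ValueError("table contains missing covariate or response values")

    feats = {
        "Sleep": table["sleep_quality"].to_numpy(dtype=float),
        "Group": table["group"].map(GROUP_CODES).to_numpy(dtype=float),
        "Eyes": table["condition"].map(EYES_CODES).to_numpy(dtype=float),
        "ML": table["ml"].to_numpy(dtype=float),
        "AP": table["ap"].to_numpy(dtype=float),
        "IS": table["is"].to_numpy(dtype=float),
    }
    if np.isnan(feats["Group"]).any():
        bad = sorted(set(table["group"]) - set(GROUP_CODES))
        raise ValueError(f"unknown group levels {bad}")
    if np.isnan(feats["Eyes"]).any():
        bad = sorted(set(table["condition"]) - set(EYES_CODES))
        raise ValueError(f"unknown eye conditions {bad}")

    combos = spec.expanded_terms()
    n = len(table)
    X = np.empty((n, len(combos)))
    for j, combo in enumerate(combos):
        col = np.ones(n)
        for f in combo:
            col = col * feats[f]
        X[:, j] = col
    participants = tuple(sorted(table["participant"].unique()))
    codes = table["participant"].map({p: i for i, p in enumerate(participants)})
    return DesignMatrices(
        y=table["log_alpha_power"].to_numpy(dtype=float),
        X=X,
        columns=tuple(_column_name(c) for c in combos),
        participant_index=codes.to_numpy(dtype=int),
        participants=participants,
        feature_values=feats,
    )


@dataclass(frozen=True)
class PosteriorDraws:
    """Post-warmup draws, kept per chain for split-chain diagnostics."""

    beta: np.ndarray  # (chains, draws, p)
    sigma: np.ndarray  # (chains, draws) residual SD
    sigma_u: np.ndarray  # (chains, draws) random-intercept SD
    u: np.ndarray  # (chains, draws, J) participant intercepts
    columns: tuple[str, ...]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])


def gibbs_sample(
    design: DesignMatrices,
    spec: ModelSpec,
    chains: int = 4,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
    fix_sigma: float | None = None,
    no_random_effects: bool = False,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Blocked Gibbs sampler over the conjugate full conditionals.

    Per sweep the fixed effects b are drawn from their multivariate
    normal conditional with the random intercepts integrated out
    (partially collapsed step, via the Woodbury identity per
    participant); then u_j | b normal, and σ², σ_u² inverse-gamma.
    Collapsing u when drawing b removes the strong posterior coupling
    between the intercept-like terms and the participant intercepts that
    otherwise cripples mixing. ``fix_sigma`` holds the residual SD at a
    known value and ``no_random_effects`` pins u = 0, σ_u = 0 — the
    combination that admits a closed-form Gaussian posterior used as the
    sampler oracle. ``prior_only`` ignores the data entirely, so draws
    come from the prior.
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    y, X, jidx = design.y, design.X, design.participant_index
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n, p = X.shape
    J = design.n_participants
    tau2 = spec.prior_sd**2
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = np.eye(p) / tau2
    n_j = np.bincount(jidx, minlength=J).astype(float)
    # per-participant sums of design rows and responses (for Woodbury)
    S = np.zeros((J, p))
    np.add.at(S, jidx, X)
    y_j = np.bincount(jidx, weights=y, minlength=J)

    kept = iterations - warmup
    out_b = np.empty((chains, kept, p))
    out_s = np.empty((chains, kept))
    out_su = np.empty((chains, kept))
    out_u = np.empty((chains, kept, J))

    root = np.random.SeedSequence([seed, 17])
    for c, child in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(child)
        b = np.zeros(p)
        u = np.zeros(J)
        sigma2 = 1.0 if fix_sigma is None else fix_sigma**2
        sigma_u2 = 1.0
        for it in range(iterations):
            if prior_only:
                b = rng.normal(0.0, spec.prior_sd, size=p)
                # IG(a0, b0) with tiny a0 is extremely heavy tailed; floor the
                # gamma draw so the reciprocal stays finite
                sigma2 = 1.0 / max(rng.gamma(spec.a0, 1.0 / spec.b0), 1e-290)
                sigma_u2 = 1.0 / max(rng.gamma(spec.a0, 1.0 / spec.b0), 1e-290)
                u = rng.normal(0.0, np.sqrt(sigma_u2), size=J)
            else:
                # b | σ, σ_u with u integrated out:
                # Σ_j⁻¹ = (I − w_j 1 1ᵀ)/σ², w_j = σ_u²/(σ² + n_j σ_u²)
                if no_random_effects:
                    w = np.zeros(J)
                else:
                    w = sigma_u2 / (sigma2 + n_j * sigma_u2)
                prec = (XtX - (S.T * w) @ S) / sigma2 + prior_prec
                rhs = (Xty - S.T @ (w * y_j)) / sigma2
                chol = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, rhs)
                z = rng.normal(size=p)
                b = mean + np.linalg.solve(chol.T, z)
                # u | b, then σ_u² | u
                if no_random_effects:
                    u = np.zeros(J)
                    sigma_u2 = 0.0
                else:
                    r_j = y_j - S @ b
                    post_var = 1.0 / (n_j / sigma2 + 1.0 / sigma_u2)
                    post_mean = post_var * r_j / sigma2
                    u = rng.normal(post_mean, np.sqrt(post_var))
                    sigma_u2 = 1.0 / rng.gamma(
                        spec.a0 + J / 2.0, 1.0 / (spec.b0 + 0.5 * np.sum(u**2))
                    )
                # σ² | rest
                if fix_sigma is None:
                    sse = np.sum((y - X @ b - u[jidx]) ** 2)
                    sigma2 = 1.0 / rng.gamma(
                        spec.a0 + n / 2.0, 1.0 / (spec.b0 + 0.5 * sse)
                    )
            if it >= warmup:
                k = it - warmup
                out_b[c, k] = b
                out_s[c, k] = np.sqrt(sigma2)
                out_su[c, k] = np.sqrt(sigma_u2)
                out_u[c, k] = u
    return PosteriorDraws(
        beta=out_b, sigma=out_s, sigma_u=out_su, u=out_u, columns=design.columns
    )


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws); each chain is split in half, and
    the classic between/within variance ratio computed on the 2m halves.
    """
    m, n = chains.shape
    if m < 2 or n < 4:
        raise ValueError("R-hat needs ≥ 2 chains of ≥ 4 draws")
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    if w <= 0:
        return 1.0
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS from autocorrelations with Geyer initial-monotone truncation."""
    m, n = chains.shape
    if m < 2 or n < 4:
        raise ValueError("ESS needs ≥ 2 chains of ≥ 4 draws")
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b / n
    if var_plus <= 0:
        return float(m * n)
    # chain-averaged autocovariance via FFT
    acov = np.zeros(n)
    for c in range(m):
        x = chains[c] - chains[c].mean()
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
        acov += ac
    acov /= m
    rho = 1.0 - (w - acov) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    t = 1
    sum_rho = 0.0
    prev = np.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        sum_rho += pair
        prev = pair
        t += 2
    ess = m * n / (1.0 + 2.0 * sum_rho)
    return float(min(ess, m * n))


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-fixed-effect R-hat and ESS."""
    if draws.beta.shape[0] < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rows = []
    for j, name in enumerate(draws.columns):
        ch = draws.beta[:, :, j]
        rows.append((name, split_rhat(ch), effective_sample_size(ch)))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])


# ---------------------------------------------------------------------------
# summaries


def evidence_stratum(pp: float) -> str:
    """Verbal evidence label for a sign posterior probability in percent.

    Boundaries are resolved by rounding to the nearest integer percent
    before lookup; values rounding above 99 are "extreme".
    """
    if not 50.0 <= pp <= 100.0:
        raise ValueError(f"PP must lie in [50, 100] percent, got {pp}")
    r = int(round(pp))
    for lo, hi, label in EVIDENCE_STRATA:
        if lo <= r <= hi:
            return label
    return "extreme"


def _summarize_draws(d: np.ndarray) -> dict:
    lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
    p_pos = np.mean(d > 0)
    pp = 100.0 * max(p_pos, 1.0 - p_pos)
    return {
        "median": float(med),
        "cri_lower": float(lo),
        "cri_upper": float(hi),
        "pp": float(pp),
        "stratum": evidence_stratum(pp),
    }


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-coefficient posterior summary table."""

    table: pd.DataFrame  # parameter, median, cri_lower, cri_upper, pp, stratum, rhat, ess

    def row(self, parameter: str) -> pd.Series:
        m = self.table[self.table["parameter"] == parameter]
        if m.empty:
            raise KeyError(f"no parameter {parameter!r} in summary")
        return m.iloc[0]

    def to_json_dict(self) -> dict:
        return {
            r["parameter"]: {
                k: r[k] for k in ("median", "cri_lower", "cri_upper", "pp", "stratum", "rhat", "ess")
            }
            for _, r in self.table.iterrows()
        }


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Median, 95% CrI, PP and evidence stratum per coefficient."""
    if draws.beta.size == 0:
        raise ValueError("no posterior draws to summarize")
    diag = diagnostics(draws).set_index("parameter")
    rows = []
    flat = draws.flat_beta()
    for j, name in enumerate(draws.columns):
        s = _summarize_draws(flat[:, j])
        s["parameter"] = name
        s["rhat"] = float(diag.loc[name, "rhat"])
        s["ess"] = float(diag.loc[name, "ess"])
        rows.append(s)
    for name, d in (("sigma", draws.sigma), ("sigma_u", draws.sigma_u)):
        s = _summarize_draws(d.reshape(-1))
        s["parameter"] = name
        s["rhat"] = float(split_rhat(d)) if d.std() > 0 else 1.0
        s["ess"] = float(effective_sample_size(d)) if d.std() > 0 else float(d.size)
        rows.append(s)
    cols = ["parameter", "median", "cri_lower", "cri_upper", "pp", "stratum", "rhat", "ess"]
    return PosteriorSummary(table=pd.DataFrame(rows)[cols])


# ---------------------------------------------------------------------------
# marginal effects


#: Percentiles of electrode coordinates defining the Left/Midline/Right,
#: Posterior/Central/Anterior and Inferior/Mid/Superior strata.
AXIS_PERCENTILES = (15.0, 50.0, 85.0)

AXIS_STRATUM_NAMES = {
    "ML": ("Left", "Midline", "Right"),
    "AP": ("Posterior", "Central", "Anterior"),
    "IS": ("Inferior", "Mid-Transverse", "Superior"),
    "Eyes": ("Closed", "Open"),
}

GROUP_NAMES = {0.0: "Abstinent", 1.0: "Non-Abstinent"}


def _sleep_terms(columns: tuple[str, ...]) -> list[tuple[int, tuple[str, ...]]]:
    """Indices and co-factors of every fixed-effect term containing Sleep."""
    out = []
    for j, name in enumerate(columns):
        factors = name.split(":") if name != "Intercept" else []
        if "Sleep" in factors:
            out.append((j, tuple(f for f in factors if f != "Sleep")))
    return out


def sleep_slope_draws(
    draws: PosteriorDraws, at: dict[str, float]
) -> np.ndarray:
    """Posterior draws of ∂E[alpha]/∂Sleep at a covariate point."""
    terms = _sleep_terms(draws.columns)
    if not terms:
        raise ValueError("model contains no Sleep effect; no slope defined")
    flat = draws.flat_beta()
    slope = np.zeros(flat.shape[0])
    for j, cofactors in terms:
        mult = 1.0
        for f in cofactors:
            mult *= at.get(f, 0.0)
        slope += flat[:, j] * mult
    return slope


def marginal_slopes(
    draws: PosteriorDraws,
    design: DesignMatrices,
    moderator: str | None = None,
    sleep_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Posterior sleep slopes per group and moderator stratum.

    ``moderator`` is one of Eyes/ML/AP/IS or None (no stratification).
    Axis strata are evaluated at the 15th/50th/85th percentiles of the
    electrode coordinate; eyes strata at closed/open. Moderators absent
    from the model yield identical slopes in every stratum. Includes the
    posterior Δ of expected alpha power over the observed sleep range.
    """
    if sleep_range is None:
        s = design.feature_values["Sleep"]
        sleep_range = (float(s.min()), float(s.max()))
    strata: list[tuple[str, dict[str, float]]]
    if moderator is None:
        strata = [("N/A", {})]
    elif moderator == "Eyes":
        strata = [("Closed", {"Eyes": 0.0}), ("Open", {"Eyes": 1.0})]
    elif moderator in ("ML", "AP", "IS"):
        vals = np.percentile(design.feature_values[moderator], AXIS_PERCENTILES)
        strata = [
            (name, {moderator: float(v)})
            for name, v in zip(AXIS_STRATUM_NAMES[moderator], vals)
        ]
    else:
        raise ValueError(f"unknown moderator {moderator!r}")
    rows = []
    span = sleep_range[1] - sleep_range[0]
    if span <= 0:
        raise ValueError("observed sleep range is degenerate")
    for g in (0.0, 1.0):
        for name, point in strata:
            at = {"Group": g, **point}
            slope = sleep_slope_draws(draws, at)
            s = _summarize_draws(slope)
            delta = np.median(slope * span)
            rows.append(
                {
                    "moderator": name,
                    "group": GROUP_NAMES[g],
                    "slope_median": s["median"],
                    "cri_lower": s["cri_lower"],
                    "cri_upper": s["cri_upper"],
                    "pp": s["pp"],
                    "stratum": s["stratum"],
                    "delta_over_range": float(delta),
                }
            )
    return pd.DataFrame(rows)


def delta_over_range(slope_draws: np.ndarray, sleep_values: np.ndarray) -> dict:
    """Δ log alpha power across the observed sleep range, per draw.

    Δ = slope × (max − min observed sleep), summarized by the median and
    95% CrI.
    """
    sleep_values = np.asarray(sleep_values, dtype=float)
    span = sleep_values.max() - sleep_values.min()
    if span <= 0:
        raise ValueError("sleep values are constant; Δ over range undefined")
    d = np.asarray(slope_draws, dtype=float) * span
    lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
    return {"delta_median": float(med), "cri_lower": float(lo), "cri_upper": float(hi)}


# ---------------------------------------------------------------------------
# posterior predictive checks


def posterior_predictive_check(
    draws: PosteriorDraws,
    design: DesignMatrices,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare observed mean/SD with replicate responses from the posterior.

    For each replicate, a posterior draw (b, u, σ) is selected at random
    and a synthetic response simulated; the report gives each statistic's
    observed value, the replicate mean, and the lower/upper tail
    probabilities P(T_rep ≥ T_obs).
    """
    if draws.beta.size == 0:
        raise ValueError("no posterior draws")
    if n_reps == 0:
        return pd.DataFrame(columns=["statistic", "observed", "rep_mean", "p_upper"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    flat_b = draws.flat_beta()
    flat_s = draws.sigma.reshape(-1)
    flat_u = draws.u.reshape(-1, draws.u.shape[-1])
    idx = rng.integers(0, flat_b.shape[0], size=n_reps)
    stats = {"mean": np.mean, "sd": lambda v: np.std(v, ddof=1)}
    obs = {k: f(design.y) for k, f in stats.items()}
    reps = {k: np.empty(n_reps) for k in stats}
    for r, i in enumerate(idx):
        mu = design.X @ flat_b[i] + flat_u[i][design.participant_index]
        y_rep = mu + rng.normal(0.0, flat_s[i], size=mu.shape)
        for k, f in stats.items():
            reps[k][r] = f(y_rep)
    rows = []
    for k in stats:
        p_upper = float(np.mean(reps[k] >= obs[k]))
        rows.append(
            {
                "statistic": k,
                "observed": float(obs[k]),
                "rep_mean": float(np.mean(reps[k])),
                "p_upper": p_upper,
            }
        )
    return pd.DataFrame(rows)
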