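"""Higher-order two-parameter logistic (2PL) IRT model.

Model
-----
Item *j* belongs to content domain *d(j)*.  The probability that
patient *i* answers it correctly is the 2PL response function

    P(y_ij = 1) = sigma(a_j * (theta_{i,d(j)} - b_j)),

with discrimination ``a_j > 0`` and difficulty ``b_j`` (no 1.7 scaling
constant).  Domain abilities load on a single general ability:

    theta_g ~ Normal(0, 1)
    theta_d = lambda_d * theta_g + eps_d,   eps_d ~ Normal(0, 1 - lambda_d^2)

so each domain ability has unit marginal variance and ``0 < lambda_d < 1``
resolves both the scale and the reflection of the latent axes.  The
posterior mean (EAP) of ``theta_g`` is the overall score; with the
two-instrument battery {DCCS, PSM} it is conventionally called SSHO2D,
with all five instruments SSHO.

Estimation is Metropolis-within-Gibbs: the general ability has a
conjugate normal full conditional and is Gibbs-sampled exactly; domain
abilities, item parameters (random walk on ``log a`` and ``b``) and
loadings use Gaussian random-walk Metropolis steps whose step sizes are
adapted during burn-in toward a 20-50% acceptance rate and frozen
afterward.  Missing responses are treated as missing at random and
skipped in the likelihood.

Priors: ``log a ~ Normal(0, 0.5^2)``, ``b ~ Normal(0, 2^2)``,
``lambda_d ~ Uniform(0, 1)`` — weakly informative and sign-identifying.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "HigherOrderStructure",
    "LatentAbilities",
    "HOIRTConfig",
    "Priors",
    "MCMCPosterior",
    "HigherOrderIRT",
    "HOIRTResults",
    "irf_2pl",
    "response_loglik",
    "simulate_hoirt",
    "fit_hoirt_mcmc",
    "eap_scores",
]


@dataclass(frozen=True)
class ItemParameters:
    """2PL parameters of a single item: discrimination, difficulty, domain."""

    a: float
    b: float
    domain: int

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"discrimination must be positive, got {self.a}")
        if self.domain < 0:
            raise ValueError(f"domain index must be non-negative, got {self.domain}")


@dataclass(frozen=True)
class HigherOrderStructure:
    """Per-domain loadings of domain ability on general ability."""

    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        for lam in self.lambdas:
            if not 0.0 < lam < 1.0:
                raise ValueError(f"loadings must lie in (0, 1), got {lam}")

    @property
    def residual_sd(self) -> np.ndarray:
        """sqrt(1 - lambda^2): keeps marginal Var(theta_d) = 1."""
        lam = np.asarray(self.lambdas)
        return np.sqrt(1.0 - lam**2)


@dataclass
class LatentAbilities:
    """General and per-domain abilities for a set of patients."""

    theta_g: np.ndarray  # (n,)
    theta_d: np.ndarray  # (n, D)


@dataclass(frozen=True)
class Priors:
    log_a_mean: float = 0.0
    log_a_sd: float = 0.5
    b_mean: float = 0.0
    b_sd: float = 2.0


@dataclass(frozen=True)
class HOIRTConfig:
    """Chain controls for :func:`fit_hoirt_mcmc`.

    ``domains`` is the ordered instrument list (two-dimensional battery
    = ("DCCS", "PSM"); five-dimensional = all five instruments).
    """

    domains: tuple[str, ...] = ("DCCS", "PSM")
    n_iter: int = 5000
    n_burn: int = 2000
    thin: int = 1
    seed: int = 0
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class MCMCPosterior:
    """Retained draws and posterior means (EAP) of every parameter."""

    chains: dict[str, np.ndarray]
    eap: dict[str, np.ndarray]
    acceptance: dict[str, float]
    config: HOIRTConfig


def irf_2pl(a: float | np.ndarray, b: float | np.ndarray, theta: float | np.ndarray) -> np.ndarray:
    """2PL item response function sigma(a * (theta - b)), strictly in (0, 1)."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination a must be positive")
    z = a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))
    out = 1.0 / (1.0 + np.exp(-z))
    if out.ndim == 0:
        return float(out)
    return out


def _bernoulli_ll_cells(R: np.ndarray, O: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-cell log Bernoulli(sigma(z)) likelihood, 0 where unobserved."""
    ll = np.where(O, np.nan_to_num(R) * z - np.logaddexp(0.0, z), 0.0)
    return ll


def response_loglik(
    responses: np.ndarray,
    items: list[ItemParameters],
    structure: HigherOrderStructure,
    abilities: LatentAbilities,
    include_prior: bool = False,
) -> float:
    """Observed-data log likelihood of a {0, 1, nan} response matrix.

    Sums log Bernoulli(irf) over observed cells; with
    ``include_prior=True`` adds the log density of the abilities under
    the higher-order structure (theta_g standard normal, theta_d normal
    around lambda_d * theta_g).
    """
    R = np.asarray(responses, dtype=float)
    n = R.shape[0]
    a = np.array([it.a for it in items])
    b = np.array([it.b for it in items])
    dom = np.array([it.domain for it in items])
    if R.shape[1] != len(items):
        raise ValueError(f"{R.shape[1]} response columns but {len(items)} items")
    theta_d = np.asarray(abilities.theta_d, dtype=float)
    if theta_d.shape[0] != n:
        raise ValueError("abilities do not match the number of patients")
    O = ~np.isnan(R)
    z = a[None, :] * (theta_d[:, dom] - b[None, :])
    total = float(_bernoulli_ll_cells(R, O, z).sum())
    if include_prior:
        lam = np.asarray(structure.lambdas)
        sd = structure.residual_sd
        tg = np.asarray(abilities.theta_g, dtype=float)
        total += float(-0.5 * np.sum(tg**2) - 0.5 * n * np.log(2 * np.pi))
        resid = theta_d - lam[None, :] * tg[:, None]
        total += float(
            np.sum(-0.5 * (resid / sd[None, :]) ** 2 - np.log(sd[None, :]) - 0.5 * np.log(2 * np.pi))
        )
    return total


def simulate_hoirt(
    items: list[ItemParameters],
    structure: HigherOrderStructure,
    n: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, LatentAbilities]:
    """Draw abilities and {0,1} responses from the generative model.

    theta_g ~ N(0, 1); theta_d = lambda_d theta_g + N(0, 1 - lambda_d^2);
    responses ~ Bernoulli(irf_2pl).  Reproducible by seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 patients")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.asarray(structure.lambdas)
    D = lam.shape[0]
    a = np.array([it.a for it in items])
    b = np.array([it.b for it in items])
    dom = np.array([it.domain for it in items])
    if dom.max() >= D:
        raise ValueError("item domain index exceeds the structure's domain count")
    theta_g = rng.standard_normal(n)
    theta_d = lam[None, :] * theta_g[:, None] + structure.residual_sd[None, :] * rng.standard_normal((n, D))
    p = irf_2pl(a[None, :], b[None, :], theta_d[:, dom])
    R = (rng.random((n, len(items))) < p).astype(float)
    return R, LatentAbilities(theta_g=theta_g, theta_d=theta_d)


class HigherOrderIRT:
    """Higher-order 2PL model bound to a response matrix.

    Parameters
    ----------
    responses : array (n_patients, n_items)
        Dichotomous responses with nan marking missing entries.
    item_domains : array (n_items,)
        Domain index of each item, 0..D-1.
    domain_names : sequence of str, optional
        Instrument names per domain; drives score naming (two domains ->
        SSHO2D/dccs2D/psm2D convention, five -> SSHO/dccs/...).
    """

    def __init__(
        self,
        responses: np.ndarray,
        item_domains: np.ndarray,
        domain_names: tuple[str, ...] | None = None,
    ) -> None:
        R = np.asarray(responses, dtype=float)
        if R.ndim != 2:
            raise ValueError("responses must be 2-D (patients x items)")
        dom = np.asarray(item_domains, dtype=int)
        if dom.shape[0] != R.shape[1]:
            raise ValueError("item_domains length must equal the item count")
        self.responses = R
        self.item_domains = dom
        self.n_domains = int(dom.max()) + 1
        if domain_names is None:
            domain_names = tuple(f"d{k}" for k in range(self.n_domains))
        if len(domain_names) != self.n_domains:
            raise ValueError("domain_names length must equal the domain count")
        self.domain_names = tuple(domain_names)
        observed = ~np.isnan(R)
        if not observed.any(axis=1).all():
            bad = int(np.flatnonzero(~observed.any(axis=1))[0])
            raise ValueError(f"patient {bad} has no observed responses")
        for d in range(self.n_domains):
            cols = dom == d
            if cols.sum() < 2:
                raise ValueError(f"domain {self.domain_names[d]} has fewer than 2 items")
            if not observed[:, cols].any():
                raise ValueError(f"domain {self.domain_names[d]} has zero observed responses")

    @classmethod
    def from_cohort(cls, records, instruments: tuple[str, ...] = ("DCCS", "PSM")) -> "HigherOrderIRT":
        """Stack per-instrument response vectors of a cohort into a model."""
        blocks, doms = [], []
        for d, name in enumerate(instruments):
            mat = np.vstack([rec.responses[name] for rec in records])
            blocks.append(mat)
            doms.append(np.full(mat.shape[1], d))
        return cls(np.hstack(blocks), np.concatenate(doms), tuple(instruments))

    # -- sampler ---------------------------------------------------------

    def fit(
        self,
        config: HOIRTConfig | None = None,
        fix_a: np.ndarray | None = None,
        fix_b: np.ndarray | None = None,
        fix_lambdas: np.ndarray | None = None,
        **config_kwargs,
    ) -> "HOIRTResults":
        """Run the Metropolis-within-Gibbs chain and return results.

        ``fix_a`` / ``fix_b`` / ``fix_lambdas`` clamp those parameter
        blocks at the given values (they are then not sampled), which is
        useful for scoring with a known item bank and in diagnostics.
        """
        if config is None:
            config = HOIRTConfig(domains=self.domain_names, **config_kwargs)
        elif config_kwargs:
            config = replace(config, **config_kwargs)
        rng = np.random.default_rng(config.seed)
        R, dom, D = self.responses, self.item_domains, self.n_domains
        n, J = R.shape
        O = ~np.isnan(R)
        Rz = np.nan_to_num(R)
        Dmat = np.zeros((J, D))
        Dmat[np.arange(J), dom] = 1.0
        pri = config.priors

        sample_items = fix_a is None and fix_b is None
        if (fix_a is None) != (fix_b is None):
            raise ValueError("fix_a and fix_b must be given together")
        sample_lam = fix_lambdas is None

        # data-driven starting values: difficulties from item facilities,
        # domain abilities from standardized number-correct scores
        if sample_items:
            p_item = np.clip(Rz.sum(axis=0) / np.maximum(O.sum(axis=0), 1), 0.02, 0.98)
            log_a = np.zeros(J)
            b = -np.log(p_item / (1.0 - p_item))
        else:
            log_a = np.log(np.asarray(fix_a, dtype=float))
            b = np.asarray(fix_b, dtype=float)
        lam = np.full(D, 0.6) if sample_lam else np.asarray(fix_lambdas, dtype=float)
        frac = (Rz @ Dmat) / np.maximum(O @ Dmat, 1)
        sd0 = frac.std(axis=0)
        th_d = np.where(sd0 > 0, (frac - frac.mean(axis=0)) / np.where(sd0 > 0, sd0, 1.0), 0.0)
        th_g = np.zeros(n)

        step_th = np.full(D, 0.8)
        step_a = np.full(J, 0.3)
        step_b = np.full(J, 0.3)
        step_lam = np.full(D, 0.1)

        def domain_ll(th: np.ndarray, a_vec: np.ndarray, b_vec: np.ndarray) -> np.ndarray:
            """Per-(patient, domain) observed log likelihood, shape (n, D)."""
            z = a_vec[None, :] * (th[:, dom] - b_vec[None, :])
            return _bernoulli_ll_cells(R, O, z) @ Dmat

        def item_ll(th: np.ndarray, a_vec: np.ndarray, b_vec: np.ndarray) -> np.ndarray:
            """Per-item observed log likelihood, shape (J,)."""
            z = a_vec[None, :] * (th[:, dom] - b_vec[None, :])
            return _bernoulli_ll_cells(R, O, z).sum(axis=0)

        K = config.n_retained
        chains = {
            "theta_g": np.empty((K, n)),
            "theta_d": np.empty((K, n, D)),
            "a": np.empty((K, J)),
            "b": np.empty((K, J)),
            "lambda": np.empty((K, D)),
        }
        acc = {"theta_d": 0.0, "items": 0.0, "lambda": 0.0}
        n_prop = {"theta_d": 0, "items": 0, "lambda": 0}
        win_acc = {"theta_d": np.zeros(D), "a": np.zeros(J), "lambda": np.zeros(D)}
        win_len = 50
        k = 0

        for it in range(config.n_iter):
            burnin = it < config.n_burn

            # theta_g | theta_d, lambda: conjugate normal Gibbs step
            w = lam**2 / (1.0 - lam**2)
            prec = 1.0 + w.sum()
            mean = (th_d * (lam / (1.0 - lam**2))[None, :]).sum(axis=1) / prec
            th_g = mean + rng.standard_normal(n) / np.sqrt(prec)

            # theta_d | rest: random-walk MH, elementwise over (patient, domain)
            prop = th_d + step_th[None, :] * rng.standard_normal((n, D))
            a_vec = np.exp(log_a)
            cur = domain_ll(th_d, a_vec, b)
            new = domain_ll(prop, a_vec, b)
            mu = lam[None, :] * th_g[:, None]
            var = (1.0 - lam**2)[None, :]
            logr = (new - cur) - 0.5 * ((prop - mu) ** 2 - (th_d - mu) ** 2) / var
            accept = np.log(rng.random((n, D))) < logr
            th_d = np.where(accept, prop, th_d)
            acc["theta_d"] += accept.mean()
            n_prop["theta_d"] += 1
            if burnin:
                win_acc["theta_d"] += accept.mean(axis=0)

            # item parameters (log a, b) | rest: joint random-walk MH per item
            if sample_items:
                la_p = log_a + step_a * rng.standard_normal(J)
                b_p = b + step_b * rng.standard_normal(J)
                cur_j = item_ll(th_d, np.exp(log_a), b)
                new_j = item_ll(th_d, np.exp(la_p), b_p)
                logr_j = (
                    (new_j - cur_j)
                    - 0.5 * ((la_p - pri.log_a_mean) ** 2 - (log_a - pri.log_a_mean) ** 2) / pri.log_a_sd**2
                    - 0.5 * ((b_p - pri.b_mean) ** 2 - (b - pri.b_mean) ** 2) / pri.b_sd**2
                )
                accept_j = np.log(rng.random(J)) < logr_j
                log_a = np.where(accept_j, la_p, log_a)
                b = np.where(accept_j, b_p, b)
                acc["items"] += accept_j.mean()
                n_prop["items"] += 1
                if burnin:
                    win_acc["a"] += accept_j

            # lambda | theta_d: collapsed MH marginalizing theta_g, so the
            # loading does not have to chase the current theta_g draw.
            # Marginally theta_d,i ~ N(0, Sigma), Sigma = lam lam' + diag(1-lam^2).
            if sample_lam:
                S = th_d.T @ th_d

                def lam_marg_ll(l: np.ndarray) -> float:
                    Sigma = np.outer(l, l) + np.diag(1.0 - l**2)
                    sign, logdet = np.linalg.slogdet(Sigma)
                    return float(-0.5 * n * logdet - 0.5 * np.trace(np.linalg.solve(Sigma, S)))

                cur_l = lam_marg_ll(lam)
                for d in range(D):
                    lam_p = lam.copy()
                    lam_p[d] += step_lam[d] * rng.standard_normal()
                    n_prop["lambda"] += 1
                    if not (0.0 < lam_p[d] < 1.0):
                        continue
                    new_l = lam_marg_ll(lam_p)
                    if np.log(rng.random()) < new_l - cur_l:
                        lam, cur_l = lam_p, new_l
                        acc["lambda"] += 1.0
                        if burnin:
                            win_acc["lambda"][d] += 1.0

            # adapt step sizes toward 20-50% acceptance, frozen after burn-in
            if burnin and (it + 1) % win_len == 0:
                for key, steps in (("theta_d", step_th), ("a", None), ("lambda", step_lam)):
                    rate = win_acc[key] / win_len
                    if key == "a":
                        step_a *= np.where(rate > 0.5, 1.2, np.where(rate < 0.2, 0.8, 1.0))
                        step_b *= np.where(rate > 0.5, 1.2, np.where(rate < 0.2, 0.8, 1.0))
                    else:
                        steps *= np.where(rate > 0.5, 1.2, np.where(rate < 0.2, 0.8, 1.0))
                    win_acc[key][:] = 0.0

            if not burnin and (it - config.n_burn) % config.thin == 0 and k < K:
                chains["theta_g"][k] = th_g
                chains["theta_d"][k] = th_d
                chains["a"][k] = np.exp(log_a)
                chains["b"][k] = b
                chains["lambda"][k] = lam
                k += 1

        eap = {name: draws[:k].mean(axis=0) for name, draws in chains.items()}
        acceptance = {key: (acc[key] / n_prop[key] if n_prop[key] else float("nan")) for key in acc}
        posterior = MCMCPosterior(
            chains={name: draws[:k] for name, draws in chains.items()},
            eap=eap,
            acceptance=acceptance,
            config=config,
        )
        return HOIRTResults(self, posterior)


class HOIRTResults:
    """Posterior summaries of a fitted higher-order 2PL model."""

    def __init__(self, model: HigherOrderIRT, posterior: MCMCPosterior) -> None:
        self.model = model
        self.posterior = posterior

    @property
    def eap_theta_g(self) -> np.ndarray:
        return self.posterior.eap["theta_g"]

    @property
    def eap_theta_d(self) -> np.ndarray:
        return self.posterior.eap["theta_d"]

    @property
    def eap_a(self) -> np.ndarray:
        return self.posterior.eap["a"]

    @property
    def eap_b(self) -> np.ndarray:
        return self.posterior.eap["b"]

    @property
    def eap_lambdas(self) -> np.ndarray:
        return self.posterior.eap["lambda"]

    def score_names(self) -> list[str]:
        names = [n.lower() for n in self.model.domain_names]
        if self.model.n_domains == 2:
            return ["SSHO2D"] + [f"{n}2D" for n in names]
        if self.model.n_domains == 5:
            return ["SSHO"] + [f"{n}5D" for n in names]
        return ["theta_g"] + names

    def scores(self) -> pd.DataFrame:
        """EAP ability scores per patient (overall score first)."""
        cols = self.score_names()
        data = np.column_stack([self.eap_theta_g, self.eap_theta_d])
        return pd.DataFrame(data, columns=cols)

    def split_chain_zscores(self) -> dict[str, float]:
        """|z| of first- vs second-half chain means (crude stationarity check)."""
        out = {}
        for name in ("lambda", "a", "b"):
            draws = self.posterior.chains.get(name)
            if draws is None or len(draws) < 4:
                continue
            h = len(draws) // 2
            first, second = draws[:h], draws[h:]
            pooled_sd = draws.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (first.mean(axis=0) - second.mean(axis=0)) / (pooled_sd * np.sqrt(2.0 / h))
            out[name] = float(np.nanmax(np.abs(z)))
        return out

    def summary(self) -> str:
        cfg = self.posterior.config
        lines = [
            "Higher-order 2PL IRT (Metropolis-within-Gibbs)",
            f"  patients: {self.model.responses.shape[0]}  items: {self.model.responses.shape[1]}"
            f"  domains: {', '.join(self.model.domain_names)}",
            f"  chain: {cfg.n_iter} iterations, {cfg.n_burn} burn-in, thin {cfg.thin}, seed {cfg.seed}",
            f"  retained draws: {len(self.posterior.chains['theta_g'])}",
            "  acceptance rates: "
            + ", ".join(f"{key}={val:.2f}" for key, val in self.posterior.acceptance.items() if np.isfinite(val)),
            "",
            "  loading (EAP) per domain:",
        ]
        for name, lam in zip(self.model.domain_names, self.eap_lambdas):
            lines.append(f"    {name:>6}: lambda = {lam:.3f}")
        a, b = self.eap_a, self.eap_b
        lines.append(
            f"  items: a in [{a.min():.2f}, {a.max():.2f}] (mean {a.mean():.2f}); "
            f"b in [{b.min():.2f}, {b.max():.2f}] (mean {b.mean():.2f})"
        )
        return "\n".join(lines)


def fit_hoirt_mcmc(
    responses: np.ndarray,
    config: HOIRTConfig,
    item_domains: np.ndarray | None = None,
    **fit_kwargs,
) -> MCMCPosterior:
    """Functional wrapper: fit the model and return the posterior.

    When ``item_domains`` is omitted the items are assigned to the
    configured domains contiguously in the battery's item-count order
    (requires the column count to match the named instruments).
    """
    if item_domains is None:
        from .instruments import INSTRUMENTS

        counts = [INSTRUMENTS[name].n_items for name in config.domains]
        if sum(counts) != np.asarray(responses).shape[1]:
            raise ValueError(
                "response column count does not match the configured instruments; "
                "pass item_domains explicitly"
            )
        item_domains = np.repeat(np.arange(len(counts)), counts)
    model = HigherOrderIRT(responses, item_domains, tuple(config.domains))
    return model.fit(config, **fit_kwargs).posterior


def eap_scores(posterior: MCMCPosterior) -> pd.DataFrame:
    """EAP scores (mean over retained draws) per patient and dimension."""
    tg = posterior.chains["theta_g"]
    td = posterior.chains["theta_d"]
    if len(tg) < 1:
        raise ValueError("posterior has no retained draws")
    names = list(posterior.config.domains)
    lower = [n.lower() for n in names]
    if len(names) == 2:
        cols = ["SSHO2D"] + [f"{n}2D" for n in lower]
    elif len(names) == 5:
        cols = ["SSHO"] + [f"{n}5D" for n in lower]
    else:
        cols = ["theta_g"] + lower
    data = np.column_stack([tg.mean(axis=0), td.mean(axis=0)])
    return pd.DataFrame(data, columns=cols)
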