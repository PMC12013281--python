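"""Hierarchical Bayesian estimation of cell-wise DDM parameters.

The model follows the statsmodels convention: :class:`HierarchicalDDM`
is built from a prepared trial table, ``fit()`` runs MCMC and returns a
:class:`HierarchicalDDMResults` carrying posterior draws, convergence
diagnostics, a ``summary()`` table, Savage-Dickey Bayes factors for
contrasts on the group-level means, and posterior plots.

Cell structure (per fitted group): starting point, drift and nondecision
time get one group-level mean per trial type x block pair; boundary
separation varies only with the block kind (random vs deterministic
block, or a single series for probabilistic material) x block pair; the
response-competition offset varies with block pair only.  Participants
contribute one random intercept per parameter, shared across cells, on
the link scale.  A linear-in-block-pair regression structure for the
group means is available as an alternative to free cell means.

Boundary coding defaults to *regularity* (upper boundary = the
sequence-predicted response, so the response boundary equals the motor
regularity of the executed key); *accuracy* coding (upper = correct
response) is available as an option.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from . import sampler
from .cohort import BASE_PARAMS, LINKS, CohortScenario, simulate_cohort
from .design import DETERMINISTIC
from .prep import filter_trials

__all__ = [
    "ModelSpec",
    "HierarchicalDDM",
    "HierarchicalDDMResults",
    "BFResult",
    "effect_bayes_factor",
    "subset_refit",
    "parameter_recovery",
    "RecoveryReport",
]

_PARAM_INDEX = {p: i for i, p in enumerate(BASE_PARAMS)}


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of the hierarchical model."""

    boundary_coding: str = "regularity"  # or "accuracy"
    mean_structure: str = "free"  # or "linear"
    share_beta_across_trial_types: bool = False
    #: (mean, sd) of the normal prior on each group-level mean, link scale
    prior_mu: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "alpha": (0.0, 1.5), "beta": (0.0, 1.5), "delta": (0.0, 2.0),
            "theta": (0.0, 1.5), "xi": (0.0, 1.5),
        }
    )
    prior_slope_sd: float = 0.5
    #: half-normal scale of the group SD priors
    prior_sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.boundary_coding not in ("regularity", "accuracy"):
            raise ValueError("boundary_coding must be 'regularity' or 'accuracy'")
        if self.mean_structure not in ("free", "linear"):
            raise ValueError("mean_structure must be 'free' or 'linear'")


@dataclass(frozen=True)
class BFResult:
    contrast: str
    bf10: float
    posterior_mean: float
    posterior_sd: float
    prior_sd: float
    bf10_kde: float  # kernel-estimate cross-check
    method: str = "savage-dickey (normal approximation)"

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _cell_keys(row_tt: str, row_kind: str, pair: int, share_beta: bool):
    """(alpha key, beta key, delta key, theta key, xi key) for one trial."""
    kstar = "deterministic" if row_kind == "deterministic" else (
        "random" if row_kind == "random" else "all"
    )
    tt = row_tt
    return (
        ("alpha", kstar, pair),
        ("beta", "all" if share_beta else tt, pair),
        ("delta", tt, pair),
        ("theta", tt, pair),
        ("xi", "all", pair),
    )


class HierarchicalDDM:
    """Hierarchical DDM over a prepared (filtered) trial table.

    The table needs columns ``participant, trial_type, block_kind,
    block_pair, rt_ms, correct, motor_regular`` and should contain one
    experimental group; trials with trial type ``undefined`` are
    rejected (run the trial filters first).
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        if (data["trial_type"] == "undefined").any():
            raise ValueError("dataset contains undefined trials; apply filter_trials first")
        participants = np.sort(data["participant"].unique())
        if len(participants) < 2:
            raise ValueError("hierarchical estimation needs at least 2 participants")
        self.participants = participants
        self.data = data.reset_index(drop=True)
        self._build()

    def _build(self) -> None:
        d = self.data
        spec = self.spec
        pid_map = {p: i for i, p in enumerate(self.participants)}
        n = len(d)
        pairs = d["block_pair"].to_numpy()
        tts = d["trial_type"].to_numpy()
        kinds = d["block_kind"].to_numpy()

        keys_per_trial = [
            _cell_keys(tts[i], kinds[i], int(pairs[i]), spec.share_beta_across_trial_types)
            for i in range(n)
        ]
        # flag cells of the full trial-type x pair grid that have no trials
        present = {k for ks in keys_per_trial for k in ks}
        all_pairs = sorted(set(int(p) for p in pairs))
        for tt in sorted(set(tts)):
            for pr in all_pairs:
                key = ("delta", tt, pr)
                if key not in present:
                    warnings.warn(f"cell {key} has zero trials and is dropped")

        if spec.mean_structure == "free":
            names: list[str] = []
            index: dict[tuple, int] = {}
            for k in sorted(present):
                index[k] = len(names)
                names.append(f"{k[0]}[{k[1]},{k[2]}]")
            cidx = np.array(
                [[index[k] for k in ks] for ks in keys_per_trial], dtype=np.int64
            )
            cidx2 = cidx.copy()
            xw = np.zeros((n, sampler.N_PARAMS))
            param_of_mu = np.array(
                [_PARAM_INDEX[k[0]] for k in sorted(present)], dtype=np.int64
            )
            prior_mean = np.array([spec.prior_mu[k[0]][0] for k in sorted(present)])
            prior_sd = np.array([spec.prior_mu[k[0]][1] for k in sorted(present)])
        else:
            # linear-in-block-pair regression: intercept at the mid pair + slope
            center = float(np.mean(all_pairs))
            series = sorted({(k[0], k[1]) for k in present})
            names = []
            index = {}
            for s in series:
                index[(*s, "icept")] = len(names)
                names.append(f"{s[0]}[{s[1]},icept]")
                index[(*s, "slope")] = len(names)
                names.append(f"{s[0]}[{s[1]},slope]")
            cidx = np.empty((n, sampler.N_PARAMS), dtype=np.int64)
            cidx2 = np.empty((n, sampler.N_PARAMS), dtype=np.int64)
            xw = np.empty((n, sampler.N_PARAMS))
            for i, ks in enumerate(keys_per_trial):
                for p, k in enumerate(ks):
                    cidx[i, p] = index[(k[0], k[1], "icept")]
                    cidx2[i, p] = index[(k[0], k[1], "slope")]
                    xw[i, p] = k[2] - center
            param_of_mu = np.empty(len(names), dtype=np.int64)
            prior_mean = np.empty(len(names))
            prior_sd = np.empty(len(names))
            for s in series:
                i0, i1 = index[(*s, "icept")], index[(*s, "slope")]
                param_of_mu[i0] = param_of_mu[i1] = _PARAM_INDEX[s[0]]
                prior_mean[i0], prior_sd[i0] = spec.prior_mu[s[0]]
                prior_mean[i1], prior_sd[i1] = 0.0, spec.prior_slope_sd
            self._center = center

        self.mu_names = names
        self._cidx, self._cidx2, self._xw = cidx, cidx2, xw
        self._param_of_mu = param_of_mu
        # slope coefficients must not take part in the recentering move
        self._shift_param = np.array(
            [-1 if name.endswith(",slope]") else int(param_of_mu[m])
             for m, name in enumerate(names)],
            dtype=np.int64,
        )
        self._prior_mean, self._prior_sd = prior_mean, prior_sd
        self._t = d["rt_ms"].to_numpy() / 1000.0
        motor = d["motor_regular"].to_numpy(dtype=bool)
        if spec.boundary_coding == "regularity":
            upper = motor.copy()
        else:
            upper = d["correct"].to_numpy(dtype=bool)
        self._upper, self._motor = upper, motor
        self._pid = np.array([pid_map[p] for p in d["participant"]], dtype=np.int64)

        # CSR maps: mu index -> affected trials, participant -> trials
        m_count = len(names)
        affected = [[] for _ in range(m_count)]
        for i in range(n):
            for p in range(sampler.N_PARAMS):
                affected[cidx[i, p]].append(i)
                if xw[i, p] != 0.0 and cidx2[i, p] != cidx[i, p]:
                    affected[cidx2[i, p]].append(i)
        self._cell_ptr = np.zeros(m_count + 1, dtype=np.int64)
        self._cell_idx = np.empty(sum(len(a) for a in affected), dtype=np.int64)
        pos = 0
        for m, a in enumerate(affected):
            self._cell_ptr[m] = pos
            self._cell_idx[pos: pos + len(a)] = a
            pos += len(a)
        self._cell_ptr[m_count] = pos
        order = np.argsort(self._pid, kind="stable")
        self._part_idx = order.astype(np.int64)
        counts = np.bincount(self._pid, minlength=len(self.participants))
        self._part_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    # -- initial values ---------------------------------------------------
    def _initial_state(self, rng: np.random.Generator):
        mu0 = np.empty(len(self.mu_names))
        for m, name in enumerate(self.mu_names):
            p = BASE_PARAMS[self._param_of_mu[m]]
            trials = self._cell_idx[self._cell_ptr[m]: self._cell_ptr[m + 1]]
            if p == "alpha":
                mu0[m] = 0.0
            elif p == "beta":
                pu = float(np.mean(self._upper[trials])) if len(trials) else 0.5
                mu0[m] = np.log(np.clip(pu, 0.1, 0.9) / (1 - np.clip(pu, 0.1, 0.9)))
            elif p == "delta":
                pu = float(np.mean(self._upper[trials])) if len(trials) else 0.5
                mu0[m] = 4.0 * (pu - 0.5)
            elif p == "theta":
                tmin = float(np.min(self._t[trials])) if len(trials) else 0.2
                mu0[m] = np.log(max(0.5 * tmin, 1e-3))
            else:
                mu0[m] = 0.0
            if "slope" in name:
                mu0[m] = 0.0
        mu0 += rng.normal(0.0, 0.02, size=mu0.shape)
        b0 = np.zeros((len(self.participants), sampler.N_PARAMS))
        sigma0 = np.full(sampler.N_PARAMS, 0.1)
        return mu0, b0, sigma0

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        n_chains: int = 2,
        n_draws: int = 1000,
        n_burn: int = 1000,
        thin: int = 2,
        seed: int = 0,
        rhat_limit: float = 1.01,
        ess_limit: float = 400.0,
    ) -> "HierarchicalDDMResults":
        """Run MCMC; warns (and flags the results) on non-convergence."""
        rng = np.random.default_rng(seed)
        mu_chains, sigma_chains, b_chains = [], [], []
        acc_mu = acc_b = None
        for chain in range(n_chains):
            mu0, b0, sigma0 = self._initial_state(rng)
            mu_d, s_d, b_d, a_mu, a_b = sampler.run_chain(
                self._t, self._upper, self._motor, self._pid,
                np.ascontiguousarray(self._cidx), np.ascontiguousarray(self._cidx2),
                np.ascontiguousarray(self._xw),
                self._cell_ptr, self._cell_idx, self._part_ptr, self._part_idx,
                self._param_of_mu, self._shift_param, self._prior_mean, self._prior_sd,
                np.full(sampler.N_PARAMS, self.spec.prior_sigma_scale),
                mu0, b0, sigma0,
                n_burn + n_draws * thin, n_burn, thin, int(seed + 1000003 * chain) % (2**31),
            )
            mu_chains.append(mu_d)
            sigma_chains.append(s_d)
            b_chains.append(b_d)
            acc_mu, acc_b = a_mu, a_b
        return HierarchicalDDMResults(
            model=self,
            mu=np.stack(mu_chains),
            sigma=np.stack(sigma_chains),
            b=np.stack(b_chains),
            seed=seed,
            rhat_limit=rhat_limit,
            ess_limit=ess_limit,
            accept_mu=acc_mu,
            accept_b=acc_b,
        )


class HierarchicalDDMResults:
    """Posterior draws, diagnostics and effect tests for a fitted model."""

    def __init__(
        self, model, mu, sigma, b, seed, rhat_limit, ess_limit, accept_mu, accept_b
    ):
        self.model = model
        self.mu = mu  # (chains, draws, M) link scale
        self.sigma = sigma
        self.b = b
        self.seed = seed
        self.accept_mu = accept_mu
        self.accept_b = accept_b
        self.idata = az.from_dict(
            posterior={
                "mu": mu,
                "sigma": sigma,
            },
            coords={"mu_name": model.mu_names, "param": list(BASE_PARAMS)},
            dims={"mu": ["mu_name"], "sigma": ["param"]},
        )
        diag = mu
        if mu.shape[0] == 1 and mu.shape[1] >= 4:
            # single chain: use split halves for R-hat / ESS
            half = mu.shape[1] // 2
            diag = np.stack([mu[0, :half], mu[0, half: 2 * half]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag_data = az.from_dict(posterior={"mu": diag})
            self.rhat = az.rhat(diag_data, var_names=["mu"])["mu"].to_numpy()
            self.ess = az.ess(diag_data, var_names=["mu"])["mu"].to_numpy()
        self.rhat_limit, self.ess_limit = rhat_limit, ess_limit
        self.convergence_ok = bool(
            np.all(self.rhat <= rhat_limit) and np.all(self.ess >= ess_limit)
        )
        if not self.convergence_ok:
            warnings.warn(
                "convergence diagnostics violated: "
                f"max R-hat {np.nanmax(self.rhat):.4f} (limit {rhat_limit}), "
                f"min ESS {np.nanmin(self.ess):.0f} (limit {ess_limit:.0f})",
                stacklevel=2,
            )

    # -- posterior tables -------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        draws = self.mu.reshape(-1, self.mu.shape[-1])
        rows = []
        for m, name in enumerate(self.model.mu_names):
            p = BASE_PARAMS[self.model._param_of_mu[m]]
            _, inv = LINKS[p]
            x = draws[:, m]
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                {
                    "name": name,
                    "param": p,
                    "mean_link": float(x.mean()),
                    "sd_link": float(x.std(ddof=1)),
                    "ci_low_link": float(lo),
                    "ci_high_link": float(hi),
                    "mean_natural": float(np.mean(inv(x))),
                    "rhat": float(self.rhat[m]),
                    "ess": float(self.ess[m]),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.params_frame()
        lines = [
            "Hierarchical DDM posterior summary (group-level means)",
            f"chains={self.mu.shape[0]} draws/chain={self.mu.shape[1]} "
            f"seed={self.seed} converged={self.convergence_ok}",
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:8.3f}",
                columns=[
                    "name", "mean_link", "sd_link", "ci_low_link", "ci_high_link",
                    "mean_natural", "rhat", "ess",
                ],
            ),
        ]
        return "\n".join(lines)

    def contrast_draws(self, weights: Mapping[str, float]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.model.mu_names)}
        missing = [n for n in weights if n not in idx]
        if missing:
            raise ValueError(f"contrast refers to unknown group means: {missing}")
        draws = self.mu.reshape(-1, self.mu.shape[-1])
        out = np.zeros(draws.shape[0])
        for name, w in weights.items():
            out += w * draws[:, idx[name]]
        return out

    def regularity_contrast(
        self, param: str, plus: str = "regular", minus: str = "nonregular"
    ) -> dict[str, float]:
        """Average over block pairs of mu[param][plus] - mu[param][minus]."""
        return regularity_contrast(self.model.mu_names, param, plus, minus)

    def save(self, out_dir) -> None:
        """Persist draws and metadata as delimited text + JSON."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        chains, draws, m = self.mu.shape
        flat = self.mu.reshape(-1, m)
        frame = pd.DataFrame(flat, columns=self.model.mu_names)
        frame.insert(0, "chain", np.repeat(np.arange(chains), draws))
        frame.to_csv(out / "mu_draws.csv", index=False)
        pd.DataFrame(
            self.sigma.reshape(-1, self.sigma.shape[-1]), columns=list(BASE_PARAMS)
        ).to_csv(out / "sigma_draws.csv", index=False)
        self.params_frame().to_csv(out / "posterior_summary.csv", index=False)
        meta = {
            "chains": int(chains),
            "draws_per_chain": int(draws),
            "seed": int(self.seed),
            "converged": self.convergence_ok,
            "rhat_limit": self.rhat_limit,
            "ess_limit": self.ess_limit,
            "boundary_coding": self.model.spec.boundary_coding,
            "mean_structure": self.model.spec.mean_structure,
        }
        with open(out / "fit_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    def bayes_factor(
        self, weights: Mapping[str, float], prior_sd: float = 0.5, label: str = ""
    ) -> BFResult:
        return effect_bayes_factor(self, weights, prior_sd, label=label)

    # -- plotting ---------------------------------------------------------
    def plot_trajectory(self, param: str, ax=None):
        """Posterior means of a parameter's cells over block pairs."""
        import matplotlib.pyplot as plt

        frame = self.params_frame()
        frame = frame[frame["param"] == param]
        if ax is None:
            _, ax = plt.subplots()
        series: dict[str, list[tuple[int, float, float, float]]] = {}
        for _, row in frame.iterrows():
            inner = row["name"].split("[", 1)[1].rstrip("]")
            tt, pair = inner.rsplit(",", 1)
            if pair in ("icept", "slope"):
                continue
            series.setdefault(tt, []).append(
                (int(pair), row["mean_natural"], row["ci_low_link"], row["ci_high_link"])
            )
        for tt, vals in sorted(series.items()):
            vals.sort()
            ax.plot([v[0] for v in vals], [v[1] for v in vals], marker="o", label=tt)
        ax.set_xlabel("block pair")
        ax.set_ylabel(param)
        ax.legend()
        return ax


def regularity_contrast(
    mu_names: Sequence[str], param: str, plus: str = "regular", minus: str = "nonregular"
) -> dict[str, float]:
    """Contrast weights: mean over block pairs of mu[plus] - mu[minus]."""
    names = [n for n in mu_names if n.startswith(f"{param}[")]
    plus_names = [n for n in names if f"[{plus}," in n]
    minus_names = [n for n in names if f"[{minus}," in n]
    if not plus_names or not minus_names:
        raise ValueError(f"no {param} cells for trial types {plus!r}/{minus!r}")
    weights = {n: 1.0 / len(plus_names) for n in plus_names}
    for n in minus_names:
        weights[n] = weights.get(n, 0.0) - 1.0 / len(minus_names)
    return weights


class PosteriorView:
    """Contrast/Bayes-factor interface over saved posterior draws."""

    def __init__(self, draws: pd.DataFrame):
        self._names = [c for c in draws.columns if c != "chain"]
        self._draws = draws[self._names].to_numpy()

    @classmethod
    def load(cls, out_dir) -> "PosteriorView":
        from pathlib import Path

        return cls(pd.read_csv(Path(out_dir) / "mu_draws.csv"))

    @property
    def mu_names(self) -> list[str]:
        return list(self._names)

    def contrast_draws(self, weights: Mapping[str, float]) -> np.ndarray:
        missing = [n for n in weights if n not in self._names]
        if missing:
            raise ValueError(f"contrast refers to unknown group means: {missing}")
        out = np.zeros(self._draws.shape[0])
        for name, w in weights.items():
            out += w * self._draws[:, self._names.index(name)]
        return out

    def regularity_contrast(self, param, plus="regular", minus="nonregular"):
        return regularity_contrast(self._names, param, plus, minus)

    def bayes_factor(self, weights, prior_sd=0.5, label=""):
        return effect_bayes_factor(self, weights, prior_sd, label=label)


def effect_bayes_factor(
    posterior: HierarchicalDDMResults,
    contrast: Mapping[str, float],
    prior_sd: float,
    label: str = "",
) -> BFResult:
    """Savage-Dickey Bayes factor for a linear contrast of group means.

    The alternative places a zero-centred normal prior (SD ``prior_sd``)
    on the contrast; BF10 is the ratio of prior to posterior density at
    zero, the posterior density via a normal approximation to the
    contrast draws with a Gaussian-kernel cross-check.
    """
    draws = posterior.contrast_draws(contrast)
    m, s = float(np.mean(draws)), float(np.std(draws, ddof=1))
    prior_at_0 = stats.norm.pdf(0.0, 0.0, prior_sd)
    post_at_0 = stats.norm.pdf(0.0, m, s)
    kde = stats.gaussian_kde(draws)
    post_at_0_kde = float(kde(0.0)[0])
    bf10 = prior_at_0 / max(post_at_0, 1e-300)
    bf10_kde = prior_at_0 / max(post_at_0_kde, 1e-300)
    return BFResult(
        contrast=label or "+".join(f"{w:+.2f}*{n}" for n, w in contrast.items()),
        bf10=float(bf10),
        posterior_mean=m,
        posterior_sd=s,
        prior_sd=prior_sd,
        bf10_kde=float(bf10_kde),
    )


def subset_refit(
    dataset: pd.DataFrame,
    awareness: Mapping[int, str],
    spec: ModelSpec | None = None,
    min_n: int = 4,
    **fit_kwargs,
) -> tuple[dict[str, HierarchicalDDMResults], pd.DataFrame]:
    """Re-estimate the model per awareness class (implicit/intermediate/explicit).

    Classes with fewer than ``min_n`` participants are skipped and
    reported.  ``awareness`` maps participant id -> class label.
    """
    results: dict[str, HierarchicalDDMResults] = {}
    report = []
    labels = pd.Series(awareness)
    for cls in sorted(set(labels.values)):
        ids = labels[labels == cls].index
        sub = dataset[dataset["participant"].isin(ids)]
        n = sub["participant"].nunique()
        if n < min_n:
            report.append({"class": cls, "n": n, "fitted": False, "reason": f"n < {min_n}"})
            continue
        model = HierarchicalDDM(sub, spec)
        results[cls] = model.fit(**fit_kwargs)
        report.append({"class": cls, "n": n, "fitted": True, "reason": ""})
    return results, pd.DataFrame(report)


@dataclass
class RecoveryReport:
    table: pd.DataFrame  # per group-level mean: truth (link), posterior mean, CI, covered
    correlation: float  # truth vs posterior mean across cells, link scale
    coverage: float  # fraction of 95% intervals covering the truth

    def __str__(self) -> str:
        return (
            f"parameter recovery: r(truth, posterior mean) = {self.correlation:.3f}, "
            f"95% CI coverage = {self.coverage:.2f}\n" + self.table.to_string(index=False)
        )


def _truth_link(scenario: CohortScenario, name: str, n_pairs: int) -> float:
    param, inner = name.split("[", 1)
    tt, pair = inner.rstrip("]").rsplit(",", 1)
    link, _ = LINKS[param]
    lookup_tt = tt
    if param == "alpha" and tt == "all":
        lookup_tt = "random"
    if tt == "all":
        lookup_tt = "nonregular" if param != "alpha" else lookup_tt
    natural = scenario.trajectory.value(param, lookup_tt, int(pair), n_pairs)
    return float(link(natural))


def parameter_recovery(
    scenario: CohortScenario,
    seed: int,
    spec: ModelSpec | None = None,
    drop_deadline_exceeded: bool = True,
    **fit_kwargs,
) -> RecoveryReport:
    """Simulate a cohort from the scenario, refit, and compare to truth.

    Truth values are the scenario's trajectory values on the link scale
    (between-participant offsets average to zero by construction).
    """
    trials, _ = simulate_cohort([scenario], seed)
    prepared, _ = filter_trials(trials, drop_deadline_exceeded=drop_deadline_exceeded)
    model = HierarchicalDDM(prepared, spec)
    fit_kwargs.setdefault("seed", seed + 1)
    res = model.fit(**fit_kwargs)
    frame = res.params_frame()
    n_pairs = scenario.config.n_block_pairs
    truths, covered = [], []
    for _, row in frame.iterrows():
        truth = _truth_link(scenario, row["name"], n_pairs)
        truths.append(truth)
        covered.append(row["ci_low_link"] <= truth <= row["ci_high_link"])
    frame = frame.assign(truth_link=truths, covered=covered)
    corr = float(np.corrcoef(frame["truth_link"], frame["mean_link"])[0, 1])
    return RecoveryReport(
        table=frame[
            ["name", "truth_link", "mean_link", "sd_link", "ci_low_link",
             "ci_high_link", "covered", "rhat", "ess"]
        ],
        correlation=corr,
        coverage=float(np.mean(covered)),
    )
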