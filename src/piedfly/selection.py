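"""Stepwise covariate selection via 85% credible intervals.

Each candidate covariate is tested in its own single-covariate model (one
fit per covariate x target rate, with stage-specific slopes); a slope is
retained when its 85% equal-tailed credible interval excludes zero, and
all retained covariates are combined into one final model, subject to the
correlation-screen exclusions.  The 85% level deliberately trades some
type-I protection for power at the screening stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import MCMCConfig, ModelSpec, PosteriorDraws, fit
from .ingest import IPMData

SURV_STAGES = ("juv", "ad")
FEC_STAGES = ("rec", "ad", "im")


@dataclass(frozen=True)
class Candidate:
    """One covariate tested on one target rate ("survival" or "fledging")."""

    covariate: str
    rate: str

    def __post_init__(self):
        if self.rate not in ("survival", "fledging"):
            raise ValueError("rate must be 'survival' or 'fledging'")


@dataclass
class SelectionTable:
    """Per (covariate, rate, stage): slope summary and retention flag."""

    table: pd.DataFrame  # columns: covariate, rate, stage, mean, lo50, hi50, lo85, hi85, retained
    draws: dict          # (covariate, rate) -> (n_draws, n_stages) slope draws

    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def credible_interval(x: np.ndarray, level: float) -> tuple:
    """Equal-tailed interval at the given level."""
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(x, alpha)), float(np.quantile(x, 1.0 - alpha)))


def select(slope_draws: np.ndarray, level: float = 0.85) -> bool:
    """Retain iff the equal-tailed CRI at ``level`` excludes zero."""
    lo, hi = credible_interval(np.asarray(slope_draws, float), level)
    return bool(lo > 0.0 or hi < 0.0)


def run_candidates(
    candidates: list,
    data: IPMData,
    config: MCMCConfig,
    base_spec: ModelSpec = ModelSpec(),
    seed: int = 0,
    level: float = 0.85,
) -> SelectionTable:
    """Fit one single-covariate model per candidate and summarize slopes.

    Each candidate gets a deterministic seed derived from the master seed,
    so candidates can be re-run in isolation.
    """
    rows = []
    all_draws = {}
    ss = np.random.SeedSequence(seed)
    cand_seeds = {
        (c.covariate, c.rate): int(s.generate_state(1)[0] % (2**31 - 1))
        for c, s in zip(candidates, ss.spawn(max(len(candidates), 1)))
    }
    for cand in candidates:
        if cand.rate == "survival":
            spec = replace(base_spec, survival_covariates=(cand.covariate,))
            stages, key = SURV_STAGES, "beta_phi"
        else:
            spec = replace(base_spec, fledging_covariates=(cand.covariate,))
            stages, key = FEC_STAGES, "beta_zeta"
        draws = fit(spec, data, config, seed=cand_seeds[(cand.covariate, cand.rate)])
        beta = draws.stacked(key)[:, 0, :]  # (ndraws, n_stages)
        all_draws[(cand.covariate, cand.rate)] = beta
        for ai, stage in enumerate(stages):
            x = beta[:, ai]
            lo50, hi50 = credible_interval(x, 0.50)
            lo85, hi85 = credible_interval(x, level)
            rows.append(
                {
                    "covariate": cand.covariate,
                    "rate": cand.rate,
                    "stage": stage,
                    "mean": float(x.mean()),
                    "lo50": lo50,
                    "hi50": hi50,
                    "lo85": lo85,
                    "hi85": hi85,
                    "retained": bool(lo85 > 0.0 or hi85 < 0.0),
                }
            )
    cols = ["covariate", "rate", "stage", "mean", "lo50", "hi50", "lo85", "hi85", "retained"]
    return SelectionTable(table=pd.DataFrame(rows, columns=cols), draws=all_draws)


def assemble_final(
    selection: SelectionTable | pd.DataFrame,
    exclusions: tuple = (),
    base_spec: ModelSpec = ModelSpec(),
) -> ModelSpec:
    """Combine every retained covariate into one model spec.

    A covariate enters a rate's set when any of its stage slopes was
    retained.  Two retained covariates that the correlation screen barred
    from co-occurring raise an error naming the pair.
    """
    table = selection.table if isinstance(selection, SelectionTable) else selection
    kept = table[table["retained"]]
    surv = tuple(sorted(kept.loc[kept["rate"] == "survival", "covariate"].unique()))
    fled = tuple(sorted(kept.loc[kept["rate"] == "fledging", "covariate"].unique()))
    present = set(surv) | set(fled)
    for pair in exclusions:
        pair = frozenset(pair)
        if pair <= present:
            a, b = sorted(pair)
            raise ValueError(
                f"retained covariates {a!r} and {b!r} exceed the correlation "
                "screening threshold and cannot enter the final model together"
            )
    return replace(
        base_spec,
        survival_covariates=surv,
        fledging_covariates=fled,
        exclusions=tuple(frozenset(p) for p in exclusions),
    )


def selection_report(selection: SelectionTable, path) -> None:
    selection.table.to_csv(path, index=False)
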