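"""Prediction scoring: posterior-predictive p-values, leave-one-out
cross-validation, and held-out accuracy accounting.

A prediction for a taxon *fails* when its observed value lies beyond 95% of
the posterior predictive distribution (p_MCMC < 0.05, two-tailed by
default); model accuracy is the fraction of taxa whose predictions pass.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ppm import (
    McmcConfig,
    PredictiveDistribution,
    SingularCovarianceError,
    fit_ppm,
    predict_tip,
    validate_trait_table,
)
from .tree import TimeTree

__all__ = ["p_mcmc", "loocv", "held_out_accuracy", "LoocvResult", "HeldOutResult"]

logger = logging.getLogger(__name__)


def p_mcmc(draws: np.ndarray, observed: float, tails: str = "two") -> float:
    """Posterior predictive p-value of an observed value.

    Two-tailed by default: ``p = 2 * min(#{draws <= obs}, #{draws >= obs}) / n``
    capped at 1, with ties counted inclusively on both sides (so a value
    inside the distribution can never score 0).  ``tails`` may be ``"two"``,
    ``"lower"`` (#{draws <= obs}/n) or ``"upper"`` (#{draws >= obs}/n).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty predictive draws")
    n = draws.size
    le = int(np.count_nonzero(draws <= observed))
    ge = int(np.count_nonzero(draws >= observed))
    if tails == "two":
        return min(2.0 * min(le, ge) / n, 1.0)
    if tails == "lower":
        return le / n
    if tails == "upper":
        return ge / n
    raise ValueError(f"unknown tail convention {tails!r}")


@dataclass(frozen=True)
class LoocvResult:
    """Per-taxon LOOCV records and the overall prediction accuracy."""

    records: pd.DataFrame  # taxon, observed, median, lo, hi, p_mcmc, passed, note
    threshold: float

    @property
    def accuracy(self) -> float:
        return float(self.records["passed"].mean())

    @property
    def failing_taxa(self) -> list[str]:
        return sorted(self.records.loc[~self.records["passed"], "taxon"])


def _fold_seed(master_seed: int, taxon: str) -> int:
    """Deterministic per-fold seed from the master seed and the taxon name,
    so folds can run in any order (or in parallel) with identical results."""
    return int((master_seed * 2654435761 + zlib.crc32(taxon.encode("utf8"))) % 2**31)


def loocv(
    tree: TimeTree,
    data: pd.DataFrame,
    config: McmcConfig | None = None,
    threshold: float = 0.05,
    estimate_lambda: bool = False,
    tails: str = "two",
) -> LoocvResult:
    """Leave-one-out cross-validation of the phylogenetic predictive model.

    For each taxon with observed y: refit on the remaining N-1, predict the
    left-out tip from its x and phylogenetic position, and score the
    observed value with ``p_mcmc``.  A fold passes when p_MCMC >= threshold
    (failure is strict ``p < threshold``).  Folds whose reduced covariance
    is singular are recorded as failed with a note rather than crashing.
    """
    config = config or McmcConfig()
    df = validate_trait_table(data)
    obs = df[np.isfinite(df["y"])]
    if len(obs) < 3:
        raise ValueError("LOOCV needs at least 3 taxa with observed y")

    rows = []
    for taxon in obs["taxon"]:
        fold = df.copy()
        idx = fold["taxon"] == taxon
        observed = float(fold.loc[idx, "y"].iloc[0])
        fold.loc[idx, "y"] = np.nan
        fold_config = replace(config, seed=_fold_seed(config.seed, taxon))
        logger.debug("LOOCV fold %s: seed %d", taxon, fold_config.seed)
        try:
            posterior = fit_ppm(tree, fold, fold_config, estimate_lambda)
            pred = predict_tip(posterior, tree, fold, taxon)
        except (SingularCovarianceError, np.linalg.LinAlgError) as exc:
            logger.warning("LOOCV fold %s failed: %s", taxon, exc)
            rows.append(
                dict(
                    taxon=taxon, observed=observed, median=np.nan, lo=np.nan,
                    hi=np.nan, p_mcmc=np.nan, passed=False, note=str(exc),
                )
            )
            continue
        p = p_mcmc(pred.draws, observed, tails=tails)
        lo, hi = pred.interval
        rows.append(
            dict(
                taxon=taxon, observed=observed, median=pred.median, lo=lo,
                hi=hi, p_mcmc=p, passed=p >= threshold, note="",
            )
        )
    return LoocvResult(records=pd.DataFrame(rows), threshold=threshold)


@dataclass(frozen=True)
class HeldOutResult:
    """Accuracy of externally supplied predictions against observed values."""

    records: pd.DataFrame
    threshold: float

    @property
    def accuracy(self) -> float:
        return float(self.records["passed"].mean())

    @property
    def failing_taxa(self) -> list[str]:
        return sorted(self.records.loc[~self.records["passed"], "taxon"])


def held_out_accuracy(
    predictions: Mapping[str, PredictiveDistribution],
    observed: Mapping[str, float],
    threshold: float = 0.05,
    tails: str = "two",
) -> HeldOutResult:
    """Apply the LOOCV pass rule to an existing set of predictions."""
    missing = sorted(set(observed) - set(predictions))
    extra = sorted(set(predictions) - set(observed))
    if missing or extra:
        raise ValueError(
            f"taxon mismatch between predictions and observations: "
            f"no prediction for {missing}, no observation for {extra}"
        )
    rows = []
    for taxon in sorted(observed):
        pred = predictions[taxon]
        p = p_mcmc(pred.draws, float(observed[taxon]), tails=tails)
        lo, hi = pred.interval
        rows.append(
            dict(
                taxon=taxon, observed=float(observed[taxon]), median=pred.median,
                lo=lo, hi=hi, p_mcmc=p, passed=p >= threshold, note="",
            )
        )
    return HeldOutResult(records=pd.DataFrame(rows), threshold=threshold)
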