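"""Consensus differential-expression calling over all replicate-pair comparisons.

Pooling noisy biological replicates into a single dispersion model can wash
out real signal when inter-replicate variation dominates.  The alternative
implemented here runs a pairwise caller on *every* control-replicate x
experiment-replicate combination (9 comparisons for 3 vs 3 replicates) and
selects the features that behave consistently across comparisons: a feature
is selected at cut-off ``n`` when a single direction (up or down) is called
significant in at least ``n`` of the pairwise comparisons.  The strictest
setting, ``n`` equal to the number of pairs, keeps only features that are
unambiguously differential in every comparison; lowering ``n`` admits more
features monotonically.

The pairwise caller is pluggable.  :func:`default_pair_caller` is a simple,
documented threshold on the pseudocount-shrunken log2 fold change; users
with real Cuffdiff output substitute per-pair ``.diff`` files read through
:func:`xyloseq.io.read_cuffdiff_diff` — the consensus logic is
caller-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .io import ExpressionMatrix, PairwiseDETable

PairCaller = Callable[[ExpressionMatrix, tuple[str, str], "CallerConfig"], PairwiseDETable]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for the default pairwise caller.

    ``alpha`` is the significance level applied when p-values are available
    (e.g. from ``.diff`` files); ``min_abs_log2fc`` is the fold-change
    threshold of the default caller; ``epsilon`` is the FPKM pseudocount
    that shrinks fold changes of poorly expressed features toward zero.
    """

    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must be in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ConfigError("min_abs_log2fc must be nonnegative")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")


@dataclass(frozen=True)
class ConsensusCall:
    """Per-feature consensus over all pairwise comparisons."""

    feature_id: str
    n_up: int
    n_down: int
    selected: bool
    consensus_direction: str  # up / down / none

    @property
    def support(self) -> int:
        return self.n_up + self.n_down


def enumerate_pairs(
    matrix: ExpressionMatrix, control_condition: str, experiment_condition: str
) -> list[tuple[str, str]]:
    """All (control replicate, experiment replicate) combinations, in
    deterministic control-major order: 3 x 3 replicates give 9 pairs."""
    controls = matrix.samples_of(control_condition)
    experiments = matrix.samples_of(experiment_condition)
    return [(c, e) for c in controls for e in experiments]


def default_pair_caller(
    matrix: ExpressionMatrix, pair: tuple[str, str], config: CallerConfig
) -> PairwiseDETable:
    """Threshold-based differential call on one replicate pair.

    log2 fold change = log2((v_exp + eps) / (v_ctl + eps)); the feature is
    significant when |log2FC| >= ``min_abs_log2fc``.  This caller has no
    statistical model, so p-values are reported as the degenerate 0
    (significant) / 1 (not) placeholders.
    """
    ctl, exp = pair
    for s in pair:
        if s not in matrix.values.columns:
            raise DesignError(f"replicate {s!r} not in matrix")
    v_ctl = matrix.values[ctl].to_numpy(dtype=float)
    v_exp = matrix.values[exp].to_numpy(dtype=float)
    eps = config.epsilon
    lfc = np.log2((v_exp + eps) / (v_ctl + eps))
    significant = np.abs(lfc) >= config.min_abs_log2fc
    direction = np.where(~significant, "none", np.where(lfc > 0, "up", "down"))
    records = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "value_control": v_ctl,
            "value_experiment": v_exp,
            "log2_fold_change": lfc,
            "p_value": np.where(significant, 0.0, 1.0),
            "q_value": np.nan,
            "significant": significant,
            "direction": direction,
        }
    )
    return PairwiseDETable(pair_label=pair, records=records)


def consensus(
    tables: Sequence[PairwiseDETable],
    cutoff_n: int,
    *,
    require_consistent_direction: bool = True,
) -> list[ConsensusCall]:
    """Tally per-feature up/down calls over all pairwise tables and select
    features whose support reaches ``cutoff_n``.

    With ``require_consistent_direction`` (the default, and the strictest
    reading of "consistent behavior"), a *single* direction must reach the
    cut-off.  Without it, total significance count is enough and the
    consensus direction is the majority one (ties give ``none``).

    Output is sorted by support descending, then feature id ascending.
    """
    if not tables:
        raise ConfigError("need at least one pairwise table")
    if not 1 <= cutoff_n <= len(tables):
        raise ConfigError(
            f"cutoff_n must be in [1, {len(tables)}], got {cutoff_n}"
        )
    universe = tables[0].feature_ids
    uset = set(universe)
    for t in tables[1:]:
        if set(t.feature_ids) != uset:
            raise DesignError("pairwise tables cover different feature universes")

    n_up = pd.Series(0, index=pd.Index(universe, name="feature_id"))
    n_down = n_up.copy()
    for t in tables:
        r = t.records
        up = r.loc[r["direction"] == "up", "feature_id"]
        down = r.loc[r["direction"] == "down", "feature_id"]
        n_up[up] += 1
        n_down[down] += 1

    calls = []
    for fid in universe:
        u, d = int(n_up[fid]), int(n_down[fid])
        if require_consistent_direction:
            if u >= cutoff_n and d == 0:
                sel, direction = True, "up"
            elif d >= cutoff_n and u == 0:
                sel, direction = True, "down"
            elif u >= cutoff_n or d >= cutoff_n:
                # one direction reaches the cut-off but the other disagrees
                sel, direction = False, "none"
            else:
                sel, direction = False, "none"
        else:
            sel = (u + d) >= cutoff_n
            direction = "up" if (sel and u > d) else "down" if (sel and d > u) else "none"
        calls.append(
            ConsensusCall(
                feature_id=fid, n_up=u, n_down=d, selected=sel, consensus_direction=direction
            )
        )
    calls.sort(key=lambda c: (-c.support, c.feature_id))
    return calls


def run_consensus_de(
    matrix: ExpressionMatrix,
    control: str,
    experiment: str,
    cutoff_n: int,
    caller: PairCaller = default_pair_caller,
    caller_config: CallerConfig | None = None,
    *,
    require_consistent_direction: bool = True,
) -> list[ConsensusCall]:
    """Full consensus pipeline on an expression matrix: enumerate every
    replicate pair, call each pair, tally, and select at ``cutoff_n``."""
    cfg = caller_config or CallerConfig()
    pairs = enumerate_pairs(matrix, control, experiment)
    tables = [caller(matrix, p, cfg) for p in pairs]
    return consensus(
        tables, cutoff_n, require_consistent_direction=require_consistent_direction
    )


def selected_genes(calls: Sequence[ConsensusCall], direction: str | None = None) -> list[str]:
    """Feature ids of selected calls, optionally restricted to one direction."""
    return [
        c.feature_id
        for c in calls
        if c.selected and (direction is None or c.consensus_direction == direction)
    ]


def calls_to_frame(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    """Tabular report: feature_id, n_up, n_down, support, consensus_direction,
    selected."""
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "n_up": [c.n_up for c in calls],
            "n_down": [c.n_down for c in calls],
            "support": [c.support for c in calls],
            "consensus_direction": [c.consensus_direction for c in calls],
            "selected": [c.selected for c in calls],
        }
    )
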