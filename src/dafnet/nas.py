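"""Exhaustive grid search over the 1-D classifier hyperparameter space.

Every candidate spec in the grid is trained once under an identical
protocol, data order and seed policy; candidates are ranked by their
best validation accuracy (the checkpointing criterion), so the search
is deterministic given the master seed.  Specs whose conv/pool stages
collapse the feature width below one SNP are recorded as infeasible
rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .models import (
    InfeasibleModelError,
    ModelSpec,
    build_1d_model,
    enumerate_grid,
    parameter_count,
)
from .training import ArraySet, RunReport, TrainConfig, TrainingError, train


@dataclass
class NASEntry:
    spec: ModelSpec
    feasible: bool
    best_val_accuracy: float  # -inf for infeasible/failed candidates
    report: Optional[RunReport] = None
    error: Optional[str] = None


@dataclass
class NASResult:
    entries: List[NASEntry]
    winner: Optional[ModelSpec]

    def to_table(self) -> str:
        """Tabular report (TSV) suitable for heat-map regeneration."""
        lines = ["n_layers\tchannels\tkernel_width\tstride\tfeasible\tbest_val_accuracy"]
        for e in self.entries:
            acc = "" if not np.isfinite(e.best_val_accuracy) else f"{e.best_val_accuracy:.4f}"
            lines.append(
                f"{e.spec.n_layers}\t{e.spec.channels}\t{e.spec.kernel_width}"
                f"\t{e.spec.stride}\t{int(e.feasible)}\t{acc}"
            )
        return "\n".join(lines)


def run_grid_search(
    train_set: ArraySet,
    val_set: ArraySet,
    config: TrainConfig,
    space: Optional[Dict[str, Sequence[int]]] = None,
    input_width: int = 128,
) -> NASResult:
    """Train every feasible candidate once and rank by validation accuracy."""
    entries: List[NASEntry] = []
    for spec in enumerate_grid(space, input_width=input_width):
        try:
            model = build_1d_model(spec, seed=config.seed)
            _, report = train(model, train_set, val_set, config)
            entries.append(NASEntry(spec, True, report.best_val_accuracy, report))
        except InfeasibleModelError as e:
            entries.append(NASEntry(spec, False, float("-inf"), error=str(e)))
        except TrainingError as e:  # candidate failure does not stop the search
            entries.append(NASEntry(spec, True, float("-inf"), error=str(e)))
    result = NASResult(entries, None)
    try:
        result.winner = select_best(result)
    except ValueError:
        pass
    return result


def select_best(result: NASResult) -> ModelSpec:
    """Argmax of best validation accuracy.

    Ties break toward fewer parameters, then fewer layers, then the
    grid's lexicographic spec order.
    """
    scored = [e for e in result.entries if np.isfinite(e.best_val_accuracy)]
    if not scored:
        raise ValueError("no feasible candidate in the search result")
    best = max(
        enumerate(scored),
        key=lambda ie: (
            ie[1].best_val_accuracy,
            -parameter_count(ie[1].spec),
            -ie[1].spec.n_layers,
            -ie[0],
        ),
    )[1]
    return best.spec


def overfitting_report(
    result: NASResult, gap_threshold: float = 0.05
) -> Dict[int, Dict]:
    """Best candidate's train/val curves per layer count.

    A model is flagged as overfit when its final-epoch train accuracy
    exceeds its final-epoch validation accuracy by more than
    ``gap_threshold``.
    """
    out: Dict[int, Dict] = {}
    for e in result.entries:
        if e.report is None:
            continue
        n = e.spec.n_layers
        if n not in out or e.best_val_accuracy > out[n]["best_val_accuracy"]:
            gap = e.report.train_accuracy[-1] - e.report.val_accuracy[-1]
            out[n] = {
                "spec": e.spec,
                "best_val_accuracy": e.best_val_accuracy,
                "train_accuracy": list(e.report.train_accuracy),
                "val_accuracy": list(e.report.val_accuracy),
                "overfit": gap > gap_threshold,
            }
    return out
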