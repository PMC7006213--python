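"""Evaluation configuration shared by the grid search and model comparison."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class EvalConfig:
    """Resampling sizes and the master seed.

    ``search_B`` bootstrap replicates score clustering-grid candidates
    (a cheaper screen); ``bootstrap_B`` replicates produce the final
    bias-corrected Harrell's C; ``cv_iters`` repetitions of
    ``cv_folds``-fold cross-validation yield the Uno's C distributions
    at the three ``horizons`` (days; 2/3/5 years by default).  All
    randomness is derived from ``seed``.
    """

    bootstrap_B: int = 500
    search_B: int = 100
    cv_iters: int = 500
    cv_folds: int = 5
    horizons: tuple = (730.0, 1095.0, 1825.0)
    seed: int = 0
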