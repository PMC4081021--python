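"""Canned selection studies: hypothesis grids and end-to-end runs.

The conversion study compares four variability hypotheses (no
subpopulations; two subpopulations differing in k1, in k2, or in k3) under
the three distribution assumptions, i.e. a 12-model grid.  The NGF study
compares no subpopulations against subpopulation-specific total-Erk
(``sErk``) or total-TrkA (``kact_T``) levels, a 9-model grid.
"""

from __future__ import annotations

import numpy as np

from .data import SnapshotDataset
from .factory import ExperimentDesign, VariabilityHypothesis, enumerate_models
from .likelihood import fit_multistart
from .mixtures import ASSUMPTIONS
from .selection import SelectionTable, rank_and_decide

__all__ = ["conversion_hypotheses", "ngf_hypotheses", "design_from_data",
           "run_selection_study"]


def conversion_hypotheses():
    """H1 (none), H2 (k1-specific), H3 (k2-specific), H4 (k3-specific)."""
    return [
        VariabilityHypothesis(1, (), name="-"),
        VariabilityHypothesis(2, ("k1",)),
        VariabilityHypothesis(2, ("k2",)),
        VariabilityHypothesis(2, ("k3",)),
    ]


def ngf_hypotheses():
    """H1 (none), H2 (total Erk via sErk), H3 (total TrkA via kact_T)."""
    return [
        VariabilityHypothesis(1, (), name="-"),
        VariabilityHypothesis(2, ("sErk",)),
        VariabilityHypothesis(2, ("kact_T",)),
    ]


def design_from_data(data: SnapshotDataset) -> ExperimentDesign:
    return ExperimentDesign(snapshots=tuple(sorted(data.snapshots)),
                            conditions=data.conditions)


def run_selection_study(data: SnapshotDataset, pathway: str,
                        hypotheses=None, assumptions=ASSUMPTIONS,
                        n_starts: int = 20, seed: int = 0,
                        refine_top: int | None = 5, threshold: float = 10.0,
                        return_fits: bool = False):
    """Fit every model of the grid to ``data`` and rank by BIC.

    Each model gets its own derived seed (``seed + model index``) so the
    whole study is reproducible from one root seed.  Returns the
    :class:`~odemix.selection.SelectionTable`, and with ``return_fits``
    also the list of (spec, FitResult) pairs.
    """
    if hypotheses is None:
        hypotheses = (conversion_hypotheses() if pathway == "conversion"
                      else ngf_hypotheses())
    specs = enumerate_models(pathway, hypotheses, assumptions,
                             design_from_data(data))
    fits = []
    for k, spec in enumerate(specs):
        fit = fit_multistart(spec, data, n_starts=n_starts,
                             seed=int(seed) + k, refine_top=refine_top)
        fits.append((spec, fit))
    table = rank_and_decide(fits, threshold=threshold)
    return (table, fits) if return_fits else table
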