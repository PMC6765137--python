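"""End-to-end pipeline: primer removal -> filter -> learn errors ->
denoise -> chimera removal.

Convenience orchestration over the library modules, mirroring the
standard long-read amplicon workflow.  Each stage is also available
individually; this module just wires them together with sensible
defaults and collects the per-stage tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import chimera as chimera_mod
from . import denoise as denoise_mod
from . import errormodel as errormodel_mod
from . import seqio
from .denoise import DadaResult
from .errormodel import ErrorModel

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    table: pd.DataFrame  # samples x ASVs, chimera-free
    raw_table: pd.DataFrame  # before chimera removal
    dada: DadaResult
    model: ErrorModel
    model_diagnostics: list
    primer_tally: dict
    filter_tally: dict
    flagged_bimeras: list
    filtered_reads: list = field(default_factory=list)


def run_pipeline(reads, primers: seqio.PrimerSpec = seqio.DEFAULT_PRIMERS,
                 filter_params: seqio.FilterParams = seqio.FilterParams(),
                 sample_name: str = "sample1",
                 n_learn: Optional[int] = 2000,
                 omega_a: float = denoise_mod.DEFAULT_OMEGA_A,
                 min_fold: float = chimera_mod.DEFAULT_MIN_FOLD,
                 model: Optional[ErrorModel] = None,
                 max_rounds: int = 10,
                 keep_reads: bool = False,
                 verbose: bool = False) -> PipelineResult:
    """Run the full single-sample workflow on raw reads.

    Primers are detected/removed and reads oriented, filtered by
    length/N-count/expected errors, the error model is learned on up to
    ``n_learn`` reads (unless a fitted ``model`` is passed), ASVs are
    inferred, and bimeras removed with the ``min_fold``
    parent-overabundance safeguard.
    """
    oriented, primer_tally = seqio.remove_primers(reads, primers)
    filtered, filter_tally = seqio.filter_reads(oriented, filter_params)
    if not filtered:
        raise ValueError("no reads survived primer removal and filtering")
    diagnostics: list = []
    if model is None:
        model, diagnostics = errormodel_mod.learn_errors(
            filtered, n_learn=n_learn, omega_a=omega_a,
            max_rounds=max_rounds, verbose=verbose)
    uniques = denoise_mod.dereplicate(filtered)
    dada = denoise_mod.run_dada(uniques, model, omega_a=omega_a)
    raw_table = denoise_mod.make_asv_table({sample_name: dada})
    table, flagged = chimera_mod.remove_bimeras(raw_table, min_fold=min_fold)
    return PipelineResult(
        table=table, raw_table=raw_table, dada=dada, model=model,
        model_diagnostics=diagnostics, primer_tally=primer_tally,
        filter_tally=filter_tally, flagged_bimeras=flagged,
        filtered_reads=filtered if keep_reads else [])
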