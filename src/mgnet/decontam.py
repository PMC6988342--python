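"""Prevalence-based contaminant screening against negative controls.

Each taxon gets a score in [0, 1]: the one-sided Fisher exact
(hypergeometric) p-value for "prevalence higher in negative controls than
in true samples", computed on the 2x2 presence table.  Small scores flag
likely contaminants; features below the classification threshold
(default 0.1, sensitivity run 0.2) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from mgnet.tables import FeatureTable, SampleMetadata, ValidationError

__all__ = ["ContaminantScore", "prevalence_score", "filter_contaminants"]


@dataclass(frozen=True)
class ContaminantScore:
    feature_id: str
    present_in_controls: int
    n_controls: int
    present_in_samples: int
    n_samples: int
    score: float
    is_contaminant: bool
    flag: str = ""


def _split_columns(table: FeatureTable, meta: Sequence[SampleMetadata]
                   ) -> tuple[list[str], list[str]]:
    by_id = {m.sample_id: m for m in meta}
    controls = [s for s in table.sample_ids
                if s in by_id and by_id[s].is_negative_control]
    samples = [s for s in table.sample_ids
               if s in by_id and not by_id[s].is_negative_control]
    return controls, samples


def prevalence_score(table: FeatureTable, meta: Sequence[SampleMetadata],
                     threshold: float = 0.1,
                     min_count: float = 0) -> list[ContaminantScore]:
    """Score every feature; presence means count > ``min_count``.

    Raises if the table has no negative-control columns (screening should
    then be skipped entirely rather than silently passed).
    """
    controls, samples = _split_columns(table, meta)
    if not controls:
        raise ValidationError(
            "no negative-control samples in table; skip contaminant "
            "screening instead of running it without controls")
    if not samples:
        raise ValidationError("no true samples in table")
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold {threshold} outside (0, 1)")
    ctrl = table.data[controls] > min_count
    samp = table.data[samples] > min_count
    scores = []
    for fid in table.feature_ids:
        a = int(ctrl.loc[fid].sum())        # present in controls
        c = int(samp.loc[fid].sum())        # present in samples
        nb_ctrl, nb_samp = len(controls), len(samples)
        flag = ""
        if a == 0 and c == 0:
            p = 1.0                          # absent everywhere: no evidence
            flag = "undefined table"
        else:
            # one-sided Fisher exact: prevalence higher in controls
            contingency = [[a, nb_ctrl - a], [c, nb_samp - c]]
            p = float(stats.fisher_exact(contingency,
                                         alternative="greater")[1])
        scores.append(ContaminantScore(
            feature_id=fid, present_in_controls=a, n_controls=nb_ctrl,
            present_in_samples=c, n_samples=nb_samp, score=min(p, 1.0),
            is_contaminant=p < threshold, flag=flag))
    return scores


def filter_contaminants(table: FeatureTable,
                        scores: Sequence[ContaminantScore],
                        meta: Sequence[SampleMetadata],
                        threshold: float = 0.1) -> FeatureTable:
    """Drop features scoring below ``threshold`` and all control columns."""
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold {threshold} outside (0, 1)")
    by_id = {s.feature_id: s for s in scores}
    missing = [f for f in table.feature_ids if f not in by_id]
    if missing:
        raise ValidationError(f"scores missing for features: {missing[:5]}")
    keep = [f for f in table.feature_ids if by_id[f].score >= threshold]
    _, samples = _split_columns(table, meta)
    return FeatureTable(table.data.loc[keep, samples], table.kind)


def scores_to_frame(scores: Sequence[ContaminantScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])
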