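"""Pooling pseudo-IPD across studies with equal per-study contribution.

When several trials inform the same arm (intervention or comparator), each
trial should contribute equally to the pooled analysis regardless of how
many patients it randomized. Records from study j of size n_j receive weight
(N/K)/n_j, where N is the combined subject count and K the number of
studies: every study's weights then sum to N/K and the total weight equals
N, so the weighted log-likelihood keeps its natural sample-size scale (which
AIC differences and covariance magnitudes rely on).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .exceptions import InputError
from .pseudo_ipd import PseudoIPD

__all__ = ["pool_arms"]


def pool_arms(trials: Sequence[PseudoIPD]) -> PseudoIPD:
    """Pool single-study pseudo-IPD sets for one arm with equal contribution.

    Parameters
    ----------
    trials
        One ``PseudoIPD`` per study, all with the same arm label, unit
        weights, and a single study label each.

    Returns
    -------
    PseudoIPD
        All records, reweighted so each study's weight sum is N_total/K.
    """
    if len(trials) == 0:
        raise InputError("pool_arms needs at least one study")
    arms = set()
    labels = []
    for trial in trials:
        studies = set(trial.study.tolist())
        if len(studies) != 1:
            raise InputError("each input must carry a single study label")
        label = studies.pop()
        if label in labels:
            raise InputError(f"duplicate study label {label!r}")
        labels.append(label)
        arms.update(trial.arm.tolist())
        if not np.allclose(trial.weight, 1.0):
            raise InputError("inputs to pooling must have unit weights")
    if len(arms) != 1:
        raise InputError(f"mixed arm labels in pooling: {sorted(map(str, arms))}")

    n_total = sum(trial.n for trial in trials)
    k = len(trials)
    per_study_weight = n_total / k

    time = np.concatenate([trial.time for trial in trials])
    event = np.concatenate([trial.event for trial in trials])
    study = np.concatenate([trial.study for trial in trials])
    arm = np.concatenate([trial.arm for trial in trials])
    weight = np.concatenate(
        [np.full(trial.n, per_study_weight / trial.n) for trial in trials]
    )
    return PseudoIPD(time=time, event=event, weight=weight, study=study, arm=arm)
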