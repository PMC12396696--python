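"""Reading, writing and preprocessing of knee-angle tables.

The canonical on-disk layout is a wide CSV with a two-row header
(participant id, group label) and one row per stride step.  A sidecar
column map (participant -> group) supports single-header files such as the
deposited study tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import TrialMatrix, ValidationError


def write_angles_csv(trials: TrialMatrix, path) -> None:
    """Write a TrialMatrix as wide CSV with (participant, group) header rows."""
    # 17 significant digits so angles round-trip bit-exactly
    trials.to_frame().to_csv(path, float_format="%.17g")


def read_angles_csv(path, group_map=None, max_steps: int = 500) -> TrialMatrix:
    """Read a wide knee-angle CSV into a validated :class:`TrialMatrix`.

    Parameters
    ----------
    path
        CSV file.  Default dialect: two header rows (participant id, group
        label) and a leading step-index column, as written by
        :func:`write_angles_csv`.
    group_map
        Optional participant -> group mapping (dict, or path to a two-column
        CSV with headers ``participant,group``).  When given, the file is
        read with a single header row of participant ids.
    max_steps
        Keep at most the first ``max_steps`` rows (the analyses focus on the
        first 500 steps: 250 baseline + 250 adaptation).
    """
    if group_map is not None:
        if not isinstance(group_map, dict):
            gm = pd.read_csv(group_map)
            cols = [c.lower() for c in gm.columns]
            gm.columns = cols
            if not {"participant", "group"} <= set(cols):
                raise ValidationError(
                    "sidecar column map needs 'participant' and 'group' columns"
                )
            group_map = dict(zip(gm["participant"].astype(str), gm["group"]))
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0].lower() in ("step", "time", "t", "index"):
            df = df.set_index(df.columns[0])
        pids = [str(c) for c in df.columns]
        missing = [p for p in pids if p not in group_map]
        if missing:
            raise ValidationError(f"unlabeled columns (no group in map): {missing}")
        groups = [group_map[p] for p in pids]
    else:
        df = pd.read_csv(path, header=[0, 1], index_col=0,
                         float_precision="round_trip")
        pids = [str(a) for a, _ in df.columns]
        groups = [str(b) for _, b in df.columns]

    df = df.iloc[:max_steps]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"missing or non-numeric angle at step row {r + 1} "
            f"(file row {df.index[r]}), participant {pids[c]!r}"
        )
    return TrialMatrix(
        angles=values,
        group_labels=np.asarray(groups, dtype=object),
        participant_ids=np.asarray(pids, dtype=object),
    )


def baseline_adjust(trials: TrialMatrix, baseline_steps=(1, 250)) -> TrialMatrix:
    """Subtract each participant's mean angle over the baseline window.

    ``baseline_steps`` is an inclusive ``(first, last)`` pair of step counts
    (values of the time index, not array positions).
    """
    lo, hi = baseline_steps
    mask = (trials.time_index >= lo) & (trials.time_index <= hi)
    if not mask.any():
        raise ValidationError("baseline window contains no steps")
    base = trials.angles[mask].mean(axis=0)
    return trials.copy_with(trials.angles - base[None, :])


def write_ground_truth_csv(truth, path) -> None:
    """Tidy ground-truth table: step, group, latent mean, noise variance."""
    rows = []
    G, T = truth.m.shape
    for j, g in enumerate(truth.groups):
        rows.append(pd.DataFrame({
            "step": np.arange(1, T + 1),
            "group": g,
            "m": truth.m[j],
            "m_realized": truth.m_realized[j],
            "sigma2": truth.sigma2[j],
            "driver": truth.driver[j],
            "true_A": truth.true_A[j],
            "true_B": truth.true_B[j],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
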