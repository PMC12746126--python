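"""Per-cell proliferation/arrest state calls.

The multivariate proliferation index (MPI) condenses three proliferation
markers (KI67, CCNA2, CCNB1) and two cell-cycle arrest markers (p21, p27)
into a three-way state: -1 when any arrest marker is positive (arrest
dominates, even if proliferation markers are expressed), +1 when any
proliferation marker is positive and no arrest marker is, and 0 otherwise.
A quiescent-cell (QCC) flag marks cells negative for KI67 and positive for
p21 and/or p27.  All calls use gate-scaled values with the strict > 0.5
positivity convention of :mod:`microscape.gating`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

PROLIFERATION_MARKERS = ("KI67", "CCNA2", "CCNB1")
ARREST_MARKERS = ("p21", "p27")
MPI_MARKERS = PROLIFERATION_MARKERS + ARREST_MARKERS

FOURWAY_LABELS = (
    "KI67+p21-p27-",
    "KI67-p21+p27-",
    "KI67-p21-p27+",
    "KI67-p21+p27+",
    "Other",
)


def _check_unit(name, values):
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size and (np.any(values < 0) or np.any(values > 1)):
        raise ValueError(f"{name} values must lie in [0, 1]")
    return values


def mpi(ki67, ccna2, ccnb1, p21, p27) -> np.ndarray:
    """Three-way proliferation state in {-1, 0, +1} from five scaled markers."""
    ki67 = _check_unit("KI67", ki67)
    ccna2 = _check_unit("CCNA2", ccna2)
    ccnb1 = _check_unit("CCNB1", ccnb1)
    p21 = _check_unit("p21", p21)
    p27 = _check_unit("p27", p27)
    arrested = (p21 > 0.5) | (p27 > 0.5)
    proliferating = (ki67 > 0.5) | (ccna2 > 0.5) | (ccnb1 > 0.5)
    out = np.zeros(ki67.shape, dtype=int)
    out[proliferating] = 1
    out[arrested] = -1  # arrest dominates proliferation
    return out


def qcc_flag(ki67, p21, p27) -> np.ndarray:
    """True iff KI67 non-positive and p21 and/or p27 positive."""
    ki67 = _check_unit("KI67", ki67)
    p21 = _check_unit("p21", p21)
    p27 = _check_unit("p27", p27)
    return (ki67 <= 0.5) & ((p21 > 0.5) | (p27 > 0.5))


def mpi_from_table(scaled: pd.DataFrame, prefix: str = "scaled_") -> pd.DataFrame:
    """MPI and QCC calls for a table with scaled_<marker> columns.

    Returns a frame with ``mpi`` and ``qcc`` plus the three positivity flags
    used by the four-way composition.
    """
    cols = {}
    for marker in MPI_MARKERS:
        col = f"{prefix}{marker}"
        if col not in scaled.columns:
            raise ValueError(f"missing required column {col!r}")
        cols[marker] = scaled[col].to_numpy(dtype=float)
    out = pd.DataFrame(index=scaled.index)
    out["mpi"] = mpi(cols["KI67"], cols["CCNA2"], cols["CCNB1"], cols["p21"], cols["p27"])
    out["qcc"] = qcc_flag(cols["KI67"], cols["p21"], cols["p27"])
    out["ki67_pos"] = cols["KI67"] > 0.5
    out["p21_pos"] = cols["p21"] > 0.5
    out["p27_pos"] = cols["p27"] > 0.5
    return out


def proliferation_index(flags) -> tuple[float, float]:
    """Fraction of positive flags with its binomial standard deviation.

    SD = sqrt(p*(1-p)/n); raises on empty input.
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("proliferation_index requires n >= 1")
    p = flags.sum() / n
    return float(p), float(math.sqrt(p * (1.0 - p) / n))


def fourway_labels(ki67_pos, p21_pos, p27_pos) -> np.ndarray:
    """Exclusive KI67/p21/p27 composition classes (Other catches the rest)."""
    ki67_pos = np.asarray(ki67_pos, dtype=bool)
    p21_pos = np.asarray(p21_pos, dtype=bool)
    p27_pos = np.asarray(p27_pos, dtype=bool)
    out = np.full(ki67_pos.shape, "Other", dtype=object)
    out[ki67_pos & ~p21_pos & ~p27_pos] = "KI67+p21-p27-"
    out[~ki67_pos & p21_pos & ~p27_pos] = "KI67-p21+p27-"
    out[~ki67_pos & ~p21_pos & p27_pos] = "KI67-p21-p27+"
    out[~ki67_pos & p21_pos & p27_pos] = "KI67-p21+p27+"
    return out


def state_composition(calls: pd.DataFrame, groups: Sequence) -> pd.DataFrame:
    """Per-group fractions of MPI states, QCC, and the four-way classes.

    ``calls`` is the output of :func:`mpi_from_table`.  Returns a tidy frame
    with columns (group, partition, state, fraction, sd, n); groups present in
    the categorical vocabulary but empty get NA rows.
    """
    calls = calls.copy()
    groups = pd.Series(groups, index=calls.index, name="group")
    if len(groups) != len(calls):
        raise ValueError("groups and calls must have equal length")
    if isinstance(groups.dtype, pd.CategoricalDtype):
        levels = list(groups.cat.categories)
    else:
        levels = sorted(pd.unique(groups.dropna()))
    calls["fourway"] = fourway_labels(
        calls["ki67_pos"], calls["p21_pos"], calls["p27_pos"]
    )
    rows = []
    for level in levels:
        mask = (groups == level).to_numpy()
        n = int(mask.sum())
        partitions = [
            ("mpi", [(1, "+1"), (0, "0"), (-1, "-1")], calls["mpi"]),
            ("qcc", [(True, "QCC"), (False, "non-QCC")], calls["qcc"]),
            ("fourway", [(lab, lab) for lab in FOURWAY_LABELS], calls["fourway"]),
        ]
        for partition, states, vec in partitions:
            vec = vec.to_numpy()
            for value, state_name in states:
                if n == 0:
                    frac, sd = float("nan"), float("nan")
                else:
                    frac = float((vec[mask] == value).sum() / n)
                    sd = math.sqrt(frac * (1 - frac) / n)
                rows.append(
                    {
                        "group": level,
                        "partition": partition,
                        "state": state_name,
                        "fraction": frac,
                        "sd": sd,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)
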