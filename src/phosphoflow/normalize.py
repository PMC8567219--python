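"""Orientation, mixing normalization and proline-conversion correction.

SILAC heavy/light ratios are log2-transformed and, where an experiment was
run with inverted labeling, negated so that positive always means higher in
the perturbed condition.  Two correction factors are then estimated
independently for each (setup, replicate) group, using unphosphorylated
peptides only:

* the mixing factor ``m`` — the mean oriented log2 ratio of proline-free
  unphosphorylated peptides, absorbing unequal amounts of heavy- and
  light-labeled cells;
* the proline-conversion factor ``c`` — metabolic conversion of heavy
  arginine into heavy proline depresses the apparent heavy signal of
  proline-containing peptides by a fixed amount per proline.  After
  subtracting ``m``, ``c`` is the average of the residual log2 ratios of
  unphosphorylated one-proline peptides pooled with the halved residuals of
  two-proline peptides (peptides with three or more prolines never enter
  the estimate but are corrected).

The corrected ratio of every peptide, phosphorylated or not, is
``oriented - m - n_prolines * c``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import NormalizationError
from .evidence_io import EvidenceRecord

logger = logging.getLogger(__name__)

GroupKey = tuple[str, str]  # (setup_id, replicate_id)


@dataclass
class NormalizationModel:
    """Fitted per-group correction factors (log2 units)."""

    mixing_factor_m: float
    proline_factor_c: float
    n_reference_peptides: int
    n_one_proline: int
    n_two_proline: int
    experiment_id: str = ""
    replicate_id: str = ""


def orient_log2(record: EvidenceRecord, swap: bool = False) -> float:
    """log2(H/L), negated when the labeling orientation is swapped."""
    if record.ratio_hl <= 0:
        raise NormalizationError(f"ratio_hl must be > 0, got {record.ratio_hl}")
    x = math.log2(record.ratio_hl)
    return -x if swap else x


def fit_normalization(
    records: Iterable[EvidenceRecord],
    swap: bool = False,
    experiment_id: str = "",
    replicate_id: str = "",
) -> NormalizationModel:
    """Fit (m, c) on one homogeneous (setup, replicate) group.

    Raises :class:`NormalizationError` when the group has no proline-free
    unphosphorylated peptide; sets ``c = 0`` with a warning when it has no
    one- or two-proline unphosphorylated peptide.
    """
    ref: list[float] = []
    one: list[float] = []
    two: list[float] = []
    for r in records:
        if r.is_phosphorylated:
            continue
        x = orient_log2(r, swap)
        if r.proline_count == 0:
            ref.append(x)
        elif r.proline_count == 1:
            one.append(x)
        elif r.proline_count == 2:
            two.append(x)
    if not ref:
        raise NormalizationError(
            f"no proline-free unphosphorylated peptides in group "
            f"({experiment_id!r}, {replicate_id!r})"
        )
    m = float(np.mean(ref))
    pooled = [x - m for x in one] + [(x - m) / 2.0 for x in two]
    if pooled:
        c = float(np.mean(pooled))
    else:
        c = 0.0
        logger.warning(
            "group (%r, %r): no 1- or 2-proline unphosphorylated peptides; "
            "proline-conversion factor set to 0",
            experiment_id, replicate_id,
        )
    return NormalizationModel(
        mixing_factor_m=m,
        proline_factor_c=c,
        n_reference_peptides=len(ref),
        n_one_proline=len(one),
        n_two_proline=len(two),
        experiment_id=experiment_id,
        replicate_id=replicate_id,
    )


def fit_groups(
    records: Sequence[EvidenceRecord],
    swap_map: Mapping[str, bool] | None = None,
    pool_replicates: bool = False,
) -> dict[GroupKey, NormalizationModel]:
    """Fit one model per (setup, replicate) group.

    ``pool_replicates`` collapses replicates of a setup into one group, for
    sparse fixtures where per-replicate fitting is under-determined.
    """
    swap_map = swap_map or {}
    groups: dict[GroupKey, list[EvidenceRecord]] = {}
    for r in records:
        key = (r.setup_id, "" if pool_replicates else r.replicate_id)
        groups.setdefault(key, []).append(r)
    models: dict[GroupKey, NormalizationModel] = {}
    for key, grp in groups.items():
        swaps = {swap_map.get(r.replicate_id, False) for r in grp}
        if len(swaps) > 1:
            raise NormalizationError(
                f"group {key} pools replicates with conflicting orientation"
            )
        models[key] = fit_normalization(
            grp, swap=swaps.pop(), experiment_id=key[0], replicate_id=key[1]
        )
    return models


def apply_normalization(
    records: Sequence[EvidenceRecord],
    models: Mapping[GroupKey, NormalizationModel],
    swap_map: Mapping[str, bool] | None = None,
    pool_replicates: bool = False,
) -> np.ndarray:
    """Correct every record: ``oriented - m - n_prolines * c``.

    Applies to phosphorylated and unphosphorylated records alike, stores the
    result on ``record.log2_corrected`` and returns the values in record
    order.  A record whose group has no fitted model is an error.
    """
    swap_map = swap_map or {}
    out = np.empty(len(records))
    for i, r in enumerate(records):
        key = (r.setup_id, "" if pool_replicates else r.replicate_id)
        model = models.get(key)
        if model is None:
            raise NormalizationError(f"no normalization model for group {key}")
        x = orient_log2(r, swap_map.get(r.replicate_id, False))
        corrected = x - model.mixing_factor_m - r.proline_count * model.proline_factor_c
        r.log2_corrected = corrected
        out[i] = corrected
    return out


def normalize_protein_level(
    records: Sequence[EvidenceRecord], protein_id: str
) -> float:
    """Center one protein's corrected ratios on its unphosphorylated median.

    Used for affinity-purification experiments where bait abundance differs
    between the conditions: every peptide of ``protein_id`` is shifted by
    minus the median corrected log2 ratio of the protein's unphosphorylated
    peptides.  Records must already carry ``log2_corrected``.  Returns the
    shift applied.
    """
    mine = [r for r in records if r.protein_id == protein_id]
    unphos = [r.log2_corrected for r in mine if not r.is_phosphorylated]
    if not unphos:
        raise NormalizationError(
            f"protein {protein_id!r} has no unphosphorylated peptide to center on"
        )
    if any(v is None for v in unphos):
        raise NormalizationError("records are not normalized yet")
    shift = float(np.median(unphos))
    for r in mine:
        r.log2_corrected = r.log2_corrected - shift
    return -shift
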