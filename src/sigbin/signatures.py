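"""Taxon-diagnostic signature-protein discovery and the two-hit sample screen.

A signature protein is present (at the homology thresholds) in at least a
configurable fraction of the target-taxon genomes and absent — zero passing
hits at the *same* thresholds — from every background genome. A metagenomic
sample is flagged as containing the taxon only when at least ``min_hits``
*distinct* signatures are detected in it (the two-hit screen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import homology
from .records import HomologyHit, ProteinRecord

__all__ = ["SignatureSet", "discover_signatures", "screen_sample"]

Proteome = Sequence[ProteinRecord]


@dataclass
class SignatureSet:
    """Discovered signature proteins with their target presence matrix."""

    signatures: list[ProteinRecord]
    presence_matrix: pd.DataFrame  # target genome (rows) x signature id (cols), bool
    presence_frac: float
    min_identity: float
    min_qcov: float

    def __post_init__(self) -> None:
        sig_ids = [s.id for s in self.signatures]
        if list(self.presence_matrix.columns) != sig_ids:
            raise ValueError("presence matrix columns do not match signature ids")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.signatures]

    def __len__(self) -> int:
        return len(self.signatures)


def _present_in(
    protein: ProteinRecord,
    proteome: Proteome,
    min_identity: float,
    min_qcov: float,
    score_floor: float,
) -> bool:
    if not proteome:
        return False
    hits = homology.search(
        [protein],
        proteome,
        min_identity=min_identity,
        min_qcov=min_qcov,
        score_floor=score_floor,
    )
    return bool(hits)


def discover_signatures(
    targets: Mapping[str, Proteome],
    background: Mapping[str, Proteome],
    *,
    presence_frac: float = 0.9,
    min_identity: float = 50.0,
    min_qcov: float = 80.0,
    score_floor: float = homology.DEFAULT_SCORE_FLOOR,
    dedup_identity: float = 95.0,
) -> SignatureSet:
    """Find proteins diagnostic of the target taxon.

    Candidates are the proteins of the lexicographically first target
    proteome. A candidate is retained when present in at least
    ``ceil(presence_frac * n_targets)`` target proteomes (the reference
    counts as present) and absent from *all* background proteomes at the
    same thresholds. Near-identical retained candidates (mutual hit at
    >= ``dedup_identity`` percent identity) are collapsed to the
    lexicographically smallest id.
    """
    if not targets:
        raise ValueError("at least one target proteome is required")
    if len(targets) < 2:
        raise ValueError("signature discovery requires >= 2 target proteomes")
    target_ids = sorted(targets)
    reference_id = target_ids[0]
    candidates = sorted(targets[reference_id], key=lambda p: p.id)
    n_required = math.ceil(presence_frac * len(target_ids))

    presence: dict[str, dict[str, bool]] = {}
    retained: list[ProteinRecord] = []
    for cand in candidates:
        row = {}
        for gid in target_ids:
            if gid == reference_id:
                row[gid] = True
            else:
                row[gid] = _present_in(
                    cand, targets[gid], min_identity, min_qcov, score_floor
                )
        if sum(row.values()) < n_required:
            continue
        absent_everywhere = all(
            not _present_in(cand, prot, min_identity, min_qcov, score_floor)
            for prot in background.values()
        )
        if not absent_everywhere:
            continue
        presence[cand.id] = row
        retained.append(cand)

    # collapse near-identical candidates, keeping the smallest id
    kept: list[ProteinRecord] = []
    for cand in retained:  # already id-sorted
        dup = False
        for k in kept:
            hit = homology.align_pair(cand, k)
            if (
                hit is not None
                and hit.identity_pct >= dedup_identity
                and hit.query_cov_pct >= min_qcov
            ):
                dup = True
                break
        if not dup:
            kept.append(cand)

    matrix = pd.DataFrame(
        [[presence[s.id][g] for s in kept] for g in target_ids],
        index=target_ids,
        columns=[s.id for s in kept],
        dtype=bool,
    )
    return SignatureSet(
        signatures=kept,
        presence_matrix=matrix,
        presence_frac=presence_frac,
        min_identity=min_identity,
        min_qcov=min_qcov,
    )


def screen_sample(
    sample_proteins: Proteome,
    sigs: SignatureSet,
    *,
    min_hits: int = 2,
    score_floor: float = homology.DEFAULT_SCORE_FLOOR,
) -> tuple[bool, list[HomologyHit]]:
    """Two-hit screen: flag a sample containing >= ``min_hits`` distinct
    signatures; the passing hits are returned to seed binning.
    """
    if not sigs.signatures:
        raise ValueError("signature set is empty")
    if not sample_proteins:
        return False, []
    hits = homology.search(
        sigs.signatures,
        sample_proteins,
        min_identity=sigs.min_identity,
        min_qcov=sigs.min_qcov,
        score_floor=score_floor,
    )
    distinct = {h.query_id for h in hits}
    return len(distinct) >= min_hits, hits
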