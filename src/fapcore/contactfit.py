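"""Evaluate predicted coevolution contacts against solenoid models.

Given ranked covariation contacts and an idealized fiber-core model, this
module computes per-contact minimum distances over all symmetry copies,
reports which top-scoring contacts the model fulfils, classifies contacts as
intra- or inter-molecular using a stacked fibril model, selects between
candidate arrangements (two-sided vs three-sided), and checks whether special
sequence motifs (e.g. the conserved CxxC of FapC) fall inside or outside the
modeled core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coupling import ContactPrediction
from .repeats import RepeatSegmentation, RoleMap
from .solenoid import ClashReport, SolenoidModel

CORE_ROLES = {"strand1", "strand2", "strand3", "arc"}


def _as_pairs(contacts) -> list[tuple[int, int, float]]:
    out = []
    for c in contacts:
        if isinstance(c, ContactPrediction):
            out.append((c.i, c.j, c.scaled_score))
        else:
            i, j = c[0], c[1]
            score = float(c[2]) if len(c) > 2 else float("nan")
            out.append((int(i), int(j), score))
    return out


def contact_distances(
    contacts,
    model: SolenoidModel,
    atom: str = "CB",
) -> np.ndarray:
    """Minimum inter-atom distance for each contact over all residue copies.

    For each pair (i, j) the distance is minimized over all monomer copies of
    both residues (fibrils are periodic, so the relevant copy pair is the
    closest one).  Residues without coordinates (outside the modeled range)
    yield NaN and are flagged by the callers rather than dropped.

    Raises
    ------
    ValueError
        If a contact index lies outside the model's sequence range.
    """
    pairs = _as_pairs(contacts)
    n_res = len(model.sequence) if model.sequence else (max(model.rung_of) if model.rung_of else 0)
    dists = np.full(len(pairs), np.nan)
    for k, (i, j, _s) in enumerate(pairs):
        if i < 1 or j < 1 or (n_res and (i > n_res or j > n_res)):
            raise ValueError(f"contact residue index {max(i, j)} outside the model sequence")
        pi = model.atom_coords(i, atom)
        pj = model.atom_coords(j, atom)
        if len(pi) == 0 or len(pj) == 0:
            continue
        diff = pi[:, None, :] - pj[None, :, :]
        dists[k] = float(np.sqrt((diff ** 2).sum(axis=2)).min())
    return dists


@dataclass
class ContactFitReport:
    """Contact-map fulfillment of a structural model.

    ``records`` has one row per contact: i, j, scaled_score, min_distance,
    fulfilled, missing, and (when classified) class.  ``fraction_fulfilled``
    is over the ``n_top`` contacts with scaled_score > score_threshold.
    """

    records: pd.DataFrame
    n_top: int
    n_fulfilled: int
    fraction_fulfilled: float
    score_threshold: float
    dist_cutoff: float
    atom: str
    intra_fraction: float | None = None


def fulfillment_report(
    contacts,
    model: SolenoidModel,
    score_threshold: float = 2.0,
    dist_cutoff: float = 8.0,
    atom: str = "CB",
) -> ContactFitReport:
    """Score-versus-distance fit of predicted contacts to a model.

    A contact is fulfilled iff its minimum distance is <= ``dist_cutoff``
    (default 8 A between pseudo-Cbeta atoms, the standard contact-prediction
    convention).  A contact whose residues have no coordinates (e.g. outside
    the modeled repeats) counts as unfulfilled and is flagged ``missing``.
    """
    pairs = _as_pairs(contacts)
    dists = contact_distances(contacts, model, atom=atom)
    missing = np.isnan(dists)
    fulfilled = ~missing & (dists <= dist_cutoff)
    scores = np.array([s for _i, _j, s in pairs])
    records = pd.DataFrame({
        "i": [p[0] for p in pairs],
        "j": [p[1] for p in pairs],
        "scaled_score": scores,
        "min_distance": dists,
        "fulfilled": fulfilled,
        "missing": missing,
    })
    top = records["scaled_score"] > score_threshold
    n_top = int(top.sum())
    n_fulfilled = int((top & records["fulfilled"]).sum())
    return ContactFitReport(
        records=records,
        n_top=n_top,
        n_fulfilled=n_fulfilled,
        fraction_fulfilled=n_fulfilled / n_top if n_top else 0.0,
        score_threshold=score_threshold,
        dist_cutoff=dist_cutoff,
        atom=atom,
    )


def classify_contacts(
    contacts,
    monomer_model: SolenoidModel,
    stacked_model: SolenoidModel,
    dist_cutoff: float = 8.0,
    atom: str = "CB",
) -> tuple[list[str], float]:
    """Label contacts as intra-, inter-molecular or unassigned.

    ``intra``: fulfilled within a single monomer; ``inter``: fulfilled only
    across monomer copies of the stacked fibril; ``unassigned``: fulfilled in
    neither.  Returns the labels and the intra fraction among assigned
    contacts (1.0 when nothing is assigned).
    """
    if stacked_model.n_monomers < 2:
        raise ValueError("stacked_model must contain more than one monomer")
    d_mono = contact_distances(contacts, monomer_model, atom=atom)
    d_stack = contact_distances(contacts, stacked_model, atom=atom)
    labels = []
    for dm, ds in zip(d_mono, d_stack):
        if not np.isnan(dm) and dm <= dist_cutoff:
            labels.append("intra")
        elif not np.isnan(ds) and ds <= dist_cutoff:
            labels.append("inter")
        else:
            labels.append("unassigned")
    n_intra = labels.count("intra")
    n_assigned = n_intra + labels.count("inter")
    intra_fraction = n_intra / n_assigned if n_assigned else 1.0
    return labels, intra_fraction


@dataclass
class ArrangementChoice:
    """Outcome of the arrangement selection with the criteria it used."""

    chosen: str
    fraction_fulfilled: dict[str, float]
    clash_counts: dict[str, int]
    tie: bool
    reason: str


def select_arrangement(
    reports: dict[str, ContactFitReport],
    clash_reports: dict[str, ClashReport] | None = None,
) -> ArrangementChoice:
    """Choose the arrangement that best fits the covariance data.

    Highest fraction of fulfilled top contacts wins; ties go to the candidate
    with fewer steric clashes; an exact tie falls back to ``two_sided`` (the
    documented default, matching the stability outcome for FapC) and is
    flagged.
    """
    if not reports:
        raise ValueError("need at least one candidate report")
    clash_reports = clash_reports or {}
    fracs = {k: r.fraction_fulfilled for k, r in reports.items()}
    clashes = {k: (clash_reports[k].count if k in clash_reports else 0)
               for k in reports}

    def sort_key(name: str):
        # two_sided preferred on exact ties
        pref = 0 if name == "two_sided" else 1
        return (-fracs[name], clashes[name], pref, name)

    ranked = sorted(reports, key=sort_key)
    chosen = ranked[0]
    tie = False
    reason = f"highest fraction_fulfilled ({fracs[chosen]:.3f})"
    if len(ranked) > 1:
        runner = ranked[1]
        if fracs[chosen] == fracs[runner]:
            if clashes[chosen] != clashes[runner]:
                reason = (f"fraction tied at {fracs[chosen]:.3f}; fewer clashes "
                          f"({clashes[chosen]} vs {clashes[runner]})")
            else:
                tie = True
                reason = (f"fraction and clash count tied; defaulting to "
                          f"{chosen}")
    return ArrangementChoice(
        chosen=chosen, fraction_fulfilled=fracs, clash_counts=clashes,
        tie=tie, reason=reason,
    )


def annotate_motif_location(
    rolemap: RoleMap,
    segmentation: RepeatSegmentation,
    motif: str = "CxxC",
) -> list[dict]:
    """Flag each occurrence of a special motif as inside or outside the core.

    An occurrence is inside the core if any of its residues carries a strand
    or arc role in the role map; occurrences confined to linkers or excluded
    flanks are outside (as observed for the conserved CxxC of FapC, which
    lies next to the large linkers rather than in the fiber core).
    """
    if rolemap.sequence != segmentation.sequence:
        raise ValueError("role map and segmentation describe different sequences")
    flags = []
    for label, s, e in segmentation.special_motifs:
        if label != motif:
            continue
        roles = {rolemap.roles[k] for k in range(s - 1, e)}
        flags.append({
            "motif": label,
            "start": s,
            "end": e,
            "inside_core": bool(roles & CORE_ROLES),
            "roles": sorted(roles),
        })
    return flags


def scatter_data(report: ContactFitReport) -> pd.DataFrame:
    """(score, distance) pairs for a score-versus-distance scatter table."""
    return report.records[["scaled_score", "min_distance"]].copy()
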