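"""Synthetic fixtures with planted ground truth.

Real inputs to the pipeline — RefSeq-scale homolog hit tables, FapC-like
repeat proteins, deep FapBC homolog alignments — are emulated here by
generators that record exactly what they planted, enabling parameter-recovery
tests: operon hit tables with clustered fap genes and scattered decoys,
repeat proteins with planted periodic repeats and Q/N-X10-Q/N anchors, and
MSAs Gibbs-sampled from a pairwise Potts model whose coupled pairs come from
a known solenoid topology.

Every generator is deterministic per seed and returns a
:class:`FixtureTruth` describing the emitted fixture exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .operon import COMPONENTS, HomologHit
from .repeats import AA20

AA = np.array(list(AA20))


@dataclass
class FixtureTruth:
    """Machine-readable ground truth emitted alongside each fixture."""

    seed: int
    planted_operons: list = field(default_factory=list)
    planted_repeats: list = field(default_factory=list)
    planted_contacts: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# operon hit tables
# ---------------------------------------------------------------------------

def gen_operon_fixture(
    seed: int,
    n_assemblies: int = 10,
    p_full_operon: float = 1.0,
    decoy_rate: float = 0.0,
    gap_distribution: tuple[int, int] = (50, 1500),
    gene_length: tuple[int, int] = (300, 1500),
    max_gap: int = 5000,
) -> tuple[list[HomologHit], FixtureTruth]:
    """Hit tables with planted operons and scattered decoys.

    Each assembly carries, with probability ``p_full_operon``, a complete
    six-gene fap operon whose intergenic gaps are drawn from
    ``gap_distribution`` (kept well under the colocalization threshold);
    otherwise it carries only a sub-threshold cluster of 2-3 fap genes (a
    realistic negative).  ``decoy_rate`` is the expected number of scattered
    decoy hits per assembly; decoys are separated from everything else by at
    least twice ``max_gap`` so truth labels are unambiguous.
    """
    if not 0 <= p_full_operon <= 1:
        raise ValueError("p_full_operon must be in [0, 1]")
    lo, hi = gap_distribution
    if not (0 <= lo <= hi):
        raise ValueError("gap_distribution must be a (low, high) bp range")
    # ensure the second-nearest-neighbor edge gap (gap + gene + gap) stays
    # below the threshold for planted operons
    if 2 * hi + gene_length[1] >= max_gap:
        raise ValueError("gap/gene ranges too wide for unambiguous planting")
    rng = np.random.default_rng(seed)
    hits: list[HomologHit] = []
    truth = FixtureTruth(seed=seed)
    for a in range(n_assemblies):
        asm = f"ASM{a:04d}"
        contig = f"{asm}_ctg1"
        taxon = f"Genus{a % max(1, n_assemblies // 2):02d}"
        pos = int(rng.integers(1000, 50000))
        full = rng.random() < p_full_operon
        comps = list(COMPONENTS) if full else \
            [COMPONENTS[k] for k in sorted(rng.choice(6, size=int(rng.integers(2, 4)),
                                                      replace=False))]
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        for c in comps:
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            start, end = pos, pos + length - 1
            hits.append(HomologHit(
                protein_id=f"{asm}_{c}", component=c, assembly_id=asm,
                contig_id=contig, start=start, end=end, strand=strand,
                taxon=taxon,
            ))
            members.append({"component": c, "start": start, "end": end})
            pos = end + 1 + int(rng.integers(lo, hi + 1))
        entry = {"assembly_id": asm, "contig_id": contig, "taxon": taxon,
                 "members": members, "passes_screen": full}
        if full:
            truth.planted_operons.append(entry)
        else:
            truth.extras.setdefault("planted_partial", []).append(entry)
        # scattered decoys, >= 2 x threshold from everything
        n_decoys = int(rng.poisson(decoy_rate))
        for d in range(n_decoys):
            pos += 2 * max_gap + int(rng.integers(0, 5000))
            c = COMPONENTS[int(rng.integers(6))]
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            hits.append(HomologHit(
                protein_id=f"{asm}_decoy{d}", component=c, assembly_id=asm,
                contig_id=contig, start=pos, end=pos + length - 1,
                strand="+" if rng.random() < 0.5 else "-", taxon=taxon,
            ))
            truth.extras.setdefault("decoys", []).append(
                {"assembly_id": asm, "component": c, "start": pos,
                 "end": pos + length - 1})
            pos += length
    return hits, truth


def hits_to_tsv(hits: list[HomologHit]) -> str:
    lines = ["\t".join(["protein_id", "component", "assembly_id", "contig_id",
                        "start", "end", "strand", "taxon"])]
    for h in hits:
        lines.append("\t".join([h.protein_id, h.component, h.assembly_id,
                                h.contig_id, str(h.start), str(h.end),
                                h.strand, h.taxon]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# repeat proteins
# ---------------------------------------------------------------------------

def gen_repeat_sequence(
    seed: int,
    period: int = 37,
    n_repeats: int = 3,
    linker_len: int = 20,
    sub_rate: float = 0.0,
    plant_qn: bool = True,
    plant_cxxc: str | None = None,
    qn_offset: int = 2,
) -> tuple[str, FixtureTruth]:
    """A repeat protein with planted periodic repeats.

    Repeats derive from a common random consensus, mutated independently at
    ``sub_rate`` per residue; they are separated (and flanked) by random
    linkers of ``linker_len`` residues.  When ``plant_qn`` is set, Q/N
    anchors are planted at in-repeat offsets (``qn_offset``,
    ``qn_offset + 11``), mirroring the conserved Q/N-X10-Q/N of CsgA/FapB/
    FapC.  ``plant_cxxc`` places a CxxC motif in a ``"linker"`` or
    ``"strand"`` (start-of-repeat) region.
    """
    if plant_qn and period < qn_offset + 12:
        raise ValueError(f"period {period} too short to plant a Q/N-X10-Q/N motif")
    if plant_cxxc not in (None, "linker", "strand"):
        raise ValueError("plant_cxxc must be None, 'linker' or 'strand'")
    if plant_cxxc == "linker" and (n_repeats < 2 or linker_len < 4):
        raise ValueError("planting CxxC in a linker needs >= 2 repeats and linker_len >= 4")
    rng = np.random.default_rng(seed)

    def rand_aa(n):
        return rng.choice(AA, size=n)

    consensus = rand_aa(period)
    if plant_qn:
        consensus[qn_offset] = rng.choice(["Q", "N"])
        consensus[qn_offset + 11] = rng.choice(["Q", "N"])

    parts, repeats = [], []
    pos = 0
    truth = FixtureTruth(seed=seed)
    for r in range(n_repeats + 1):
        link = rand_aa(linker_len)
        parts.append(link)
        pos += linker_len
        if r < n_repeats:
            rep = consensus.copy()
            if sub_rate > 0:
                mutate = rng.random(period) < sub_rate
                for k in np.flatnonzero(mutate):
                    choices = [a for a in AA20 if a != rep[k]]
                    rep[k] = choices[int(rng.integers(len(choices)))]
            parts.append(rep)
            repeats.append((pos + 1, pos + period))
            pos += period
    seq = np.concatenate(parts)

    cxxc_interval = None
    if plant_cxxc == "linker":
        # centre of the first internal linker
        start = repeats[0][1] + max(0, (linker_len - 4) // 2)  # 0-based index
        seq[start:start + 4] = list("CAAC")
        cxxc_interval = (start + 1, start + 4)
    elif plant_cxxc == "strand":
        start = repeats[min(1, n_repeats - 1)][0] - 1  # start of a repeat = strand1
        seq[start:start + 4] = list("CAAC")
        cxxc_interval = (start + 1, start + 4)

    truth.planted_repeats = [{"start": s, "end": e} for s, e in repeats]
    truth.extras = {
        "period": period,
        "consensus": "".join(consensus),
        "qn_anchors": ([(qn_offset + 1, qn_offset + 12)] if plant_qn else []),
        "cxxc": cxxc_interval,
        "sub_rate": sub_rate,
    }
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# Potts-sampled MSAs
# ---------------------------------------------------------------------------

def sample_potts_msa(
    topology_contacts: list[tuple[int, int]],
    L: int,
    n_seqs: int,
    coupling_strength: float = 2.0,
    seed: int = 0,
    n_sweeps: int = 1000,
) -> tuple[list[str], FixtureTruth]:
    """Gibbs-sample sequences from a pairwise Potts model with planted pairs.

    The model has zero fields and ferromagnetic couplings
    ``J_ij(a, b) = coupling_strength * [a == b]`` on the given contact pairs
    (0-based indices), zero elsewhere, over the 20 amino-acid states.  One
    independent Gibbs chain per sequence is burned in for ``n_sweeps``
    full sweeps over the coupled sites (uncoupled sites are exactly uniform
    and are drawn directly), so samples are independent across sequences.
    """
    q = 20
    for i, j in topology_contacts:
        if not (0 <= i < L and 0 <= j < L) or i == j:
            raise ValueError(f"invalid contact pair ({i}, {j}) for L={L}")
    if coupling_strength < 0:
        raise ValueError("coupling_strength must be >= 0")
    rng = np.random.default_rng(seed)
    partners: dict[int, list[int]] = {}
    for i, j in topology_contacts:
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    coupled = sorted(partners)

    # chromatic Gibbs: non-adjacent sites share no conditional dependence and
    # are updated in one vectorized step per color
    color_of: dict[int, int] = {}
    for site in coupled:
        used = {color_of[j] for j in partners[site] if j in color_of}
        color_of[site] = next(c for c in range(len(coupled)) if c not in used)
    colors: dict[int, list[int]] = {}
    for site, c in color_of.items():
        colors.setdefault(c, []).append(site)
    batches = []
    for c in sorted(colors):
        sites = sorted(colors[c])
        pos_of = {s: k for k, s in enumerate(sites)}
        edges = [(pos_of[s], j) for s in sites for j in partners[s]]
        batches.append((np.array(sites), edges))

    X = rng.integers(0, q, size=(n_seqs, L), dtype=np.int64)
    if coupling_strength > 0 and coupled:
        rows = np.arange(n_seqs)
        for _ in range(n_sweeps):
            for sites, edges in batches:
                E = np.zeros((n_seqs, len(sites), q))
                for pos, j in edges:
                    Epos = E[:, pos, :]
                    Epos[rows, X[:, j]] += coupling_strength
                P = np.exp(E - E.max(axis=2, keepdims=True))
                P /= P.sum(axis=2, keepdims=True)
                u = rng.random((n_seqs, len(sites)))
                X[:, sites] = (P.cumsum(axis=2) < u[:, :, None]).sum(axis=2)
    seqs = ["".join(AA20[s] for s in row) for row in X]
    truth = FixtureTruth(
        seed=seed,
        planted_contacts=[{"i": int(i), "j": int(j),
                           "strength": float(coupling_strength)}
                          for i, j in topology_contacts],
        extras={"L": L, "n_seqs": n_seqs, "n_sweeps": n_sweeps},
    )
    return seqs, truth


def msa_to_fasta(seqs: list[str], prefix: str = "seq") -> str:
    return "".join(f">{prefix}{n}\n{s}\n" for n, s in enumerate(seqs))


def topology_contact_pairs(
    model,
    dist_cutoff: float = 8.0,
    min_separation: int = 5,
    atom: str = "CB",
) -> list[tuple[int, int]]:
    """Harvest intra-monomer contact pairs (0-based) from a solenoid model.

    Used to plant topology-derived couplings: all residue pairs whose chosen
    atoms lie within ``dist_cutoff`` in the monomer, at sequence separation
    >= ``min_separation``.
    """
    residues = sorted(model.rung_of)
    pairs = []
    for a_idx, i in enumerate(residues):
        pi = model.atom_coords(i, atom)
        if len(pi) == 0:
            continue
        for j in residues[a_idx + 1:]:
            if abs(j - i) < min_separation:
                continue
            pj = model.atom_coords(j, atom)
            if len(pj) == 0:
                continue
            diff = pi[:, None, :] - pj[None, :, :]
            if np.sqrt((diff ** 2).sum(axis=2)).min() <= dist_cutoff:
                pairs.append((i - 1, j - 1))
    return pairs
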