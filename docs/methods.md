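# Methods

`fapcore` implements the in-silico arm of a structural study of the
Pseudomonas functional amyloid (Fap) system: screening genome collections
for *fap*-operon homologs, characterising the repeat architecture of the
fiber subunits (FapB/FapC and their curli counterpart CsgA), predicting
residue–residue contacts from sequence covariance, and testing idealized
β-solenoid models of the FapC fiber core against those contacts.

## Operon colocalization screen

Homology searches over large genome collections produce many isolated,
spurious hits. A hit is treated as part of a genuine *fap* operon only if its
**second-nearest** *fap*-gene neighbor on the same contig lies within
`max_gap` (default 5000 bp), i.e. at least two other *fap* hits fall within
that distance. Retained hits are single-linkage clustered at `max_gap`, and a
cluster is called an operon when it carries at least `min_components = 4`
distinct Fap components (FapA–FapF).

Choices the screen fixes, each switchable:

* **Gap metric** — edge-to-edge intergenic distance, 0 for overlapping
  features (`gap_metric="midpoint"` gives midpoint distance instead). The
  edge convention is the strictest common reading of "< 5000 bp apart".
* **Component counting** — distinct components, so tandem fragments of one
  gene cannot satisfy the threshold (`count_raw_hits=True` counts hits).
* Strand is recorded but ignored by the filter; duplicates are dropped only
  on identical `(protein_id, contig, start, end)`.
* Hits are grouped by `(assembly_id, contig_id)`, so equal contig names in
  different assemblies never merge.

The same gap rule powers `detect_colocalized_pairs`, used for the conserved
FapD–FapF gene pairing found outside complete operons. `presence_matrix`
summarises calls per taxon with strain counts (distinct assemblies with at
least one call).

## Repeat architecture

FapC carries three imperfect ~37-residue repeats separated by long variable
linkers; CsgA repeats are ~22 residues. `segment_repeats` finds them without
a motif library:

1. **Detection gate.** The BLOSUM62 self-alignment score of the best
   contiguous run over all lags is compared against the same max-statistic on
   `n_shuffles = 100` shuffled copies of the sequence; detection requires
   mean + 3.5 SD. Calibrating the *selected* maximum (not a fixed unit)
   controls false positives on random sequences at ~1% (measured 1/200).
2. **Unit extraction.** The dominant run yields a candidate unit; its length
   is capped at the lag so tandem repeats do not produce doubled units. A
   user-supplied `expected_period` overrides the unit length.
3. **Occurrence scan.** The unit (then its majority-rule consensus over
   found occurrences) is scanned ungapped across the sequence; greedy
   non-overlapping peaks above a shuffle-calibrated threshold become repeats.
   In auto-period mode, consensus columns with cross-occurrence conservation
   below 0.5 (smoothed) are trimmed from the flanks, shedding linker residues
   swallowed into a repeat-plus-linker unit.
4. **Phase polish.** A common boundary offset (picked up when a chance
   alignment extends the run into a linker) is removed by sliding a
   unit-length window ±6 residues and maximising cross-occurrence
   conservation over interior occurrences.

On planted fixtures (3 × 37-residue repeats, 20-residue linkers, 10%
substitutions) the mean absolute boundary error is ≈ 0.1 residues over 50
seeds. The procedure assumes substitution-style divergence between repeat
copies; indel-divergent repeats would need gapped scanning and are out of
scope.

`find_qn_motifs` reports every Q/N-X10-Q/N anchor pair (both anchors Q or N,
exactly ten residues between), overlaps included — the motif conserved across
CsgA, FapB and FapC. `find_cxxc` locates CxxC sites.

`assign_roles` turns a segmentation into per-residue solenoid roles: each
repeat becomes one rung, split into 2 (two-sided) or 3 (three-sided) strands
joined by `arc_length`-residue turns, one turn after every strand (the
trailing turn closes the rung onto the next). Uneven splits give the longer
strand first. Default arc lengths (5 two-sided, 4 three-sided) make a
37-residue rung yield 13–14-residue strands, consistent with the measured
fiber-core width. Residues between repeats are `linker`; flanks outside the
repeat region are `excluded` and get no coordinates.

## Sequence covariance

Contact prediction follows standard direct-coupling analysis over 21 states
(20 amino acids + gap):

* **Reweighting** — weight 1/(number of sequences at ≥ 80% identity,
  identity over both-non-gap columns); the weight sum is the effective
  sequence count.
* **Masking** — columns with > 50% gaps, columns gapped in the reference
  (first) sequence, and constant columns are excluded from fitting; indices
  are always reported in ungapped reference numbering.
* **MI-APC baseline** — weighted mutual information with one pseudocount
  per joint state cell (marginals from the smoothed joint, so MI ≥ 0),
  followed by average-product correction (APC),
  `S_ij − S_i·S_j / S̄` with row means excluding the diagonal.
* **Pseudolikelihood Potts fit** — the symmetric parameterization (fields +
  upper-triangle coupling blocks) maximizes the L2-regularized sum of
  site-wise conditional log-likelihoods with L-BFGS from zero
  initialization; deterministic, no randomness. Defaults:
  `lambda_h = 0.01`, `lambda_J = 0.1·(L−1)`, `max_iter = 100`,
  gradient tolerance 1e-3 — ample for ranking couplings, which is all the
  downstream analysis consumes. Non-convergence sets a flag and warns.
* **Scoring** — raw score = Frobenius norm of the zero-sum-gauge 20×20
  (gap-excluded) coupling block; APC on the raw matrix.

**Scaled score convention.** Published "Gremlin scores" are on an
average-signal scale without a published definition. Here the APC-corrected
scores are first soft-thresholded at 2 robust standard deviations (1.4826 ×
MAD): values within the noise band collapse to zero, the rest shift down by
the band edge. Survivors are normalized so their positive mean is 1. On this
scale "> 2.0" means "twice the average significant coupling signal";
alignments with no covariance structure produce essentially no scores above
2 (< 1% of pairs, measured 0–0.6%), while pairs planted at coupling strength
2.0 score ≈ 2.2–3.3. The two simpler conventions fail one side each:
dividing APC scores by their positive mean leaves a ~5% null tail above 2.0
(the ratio is scale-free), and dividing raw norms by their mean buries real
couplings under the shared noise floor (planted pairs reach only ~1.8× the
mean). Ranking is by scaled score, ties by APC score, then (i, j).

## Idealized β-solenoid builder

Each rung is laid out in the cross-sectional (xy) plane and stacked along
the fibril axis (+z) at the cross-β spacing. Geometry constants are textbook
cross-β values, all configurable via `GeometryParams`:

| parameter | default | meaning |
|---|---|---|
| `ca_step` | 3.8 Å | consecutive in-strand Cα distance |
| `axial_projection` | 3.45 Å | per-residue advance along the strand axis |
| `rung_rise` | 4.75 Å | rung stacking distance along the fibril axis |
| `sheet_separation` | 10.0 Å | Cα–Cα distance between opposing sheets |
| `cb_offset` | 1.5 Å | pseudo-Cβ displacement off the Cα |
| `arc_bulge` | 2.0 Å | outward sagitta budget of width-constrained turns |
| `corner_margin` | 8.0 Å | strand setback from triangle vertices (3-sided) |
| `loop_standoff` | 6.0 Å | clearance of linker loops from the core |

Strands are pleated: Cα alternate ±√(`ca_step`² − `axial_projection`²)/2
along the sheet normal so consecutive Cα are exactly `ca_step` apart while
advancing `axial_projection` along the strand. The pleat phase is anchored
at each rung's first residue — not global sequence parity — so equivalent
residues of successive rungs are exact translates even for odd repeat
lengths. Pseudo-Cβ sit `cb_offset` further along the same normal,
alternating into/out of the core; turn and loop Cβ all point outward.

Turns between strands adapt to how much chain must cross how large a gap:

* **Shallow/petal turns** — a circular arc through the anchor points. Where
  the full-bond-length arc's sagitta fits the bulge budget it is used
  directly (at three-sided corners, where space outside the triangle is
  free, this gives outward "petal" turns); otherwise a flatter arc with
  sagitta ≤ `arc_bulge` is used if atoms still sit ≥ ~3 Å apart.
* **Waypoint turns** — when the chain is crowded (e.g. five arc residues
  across a 10 Å sheet gap), the chain escapes each junction with a
  full-length step directed outward and to the inter-rung midplane
  (`rung_rise`/2), clearing both the strand-end pseudo-Cβ of its own rung
  and the strand ends of the neighboring rung, and the remaining residues
  bridge the two escape points. Slack is absorbed along the fibril axis,
  keeping the cross-section compact.

A turn whose residues cannot span the sheet gap even at full bond length
raises an error. Inter-repeat linkers are rendered as coarse circular
excursion loops outside the core (circumference matched to chain length,
stood off `loop_standoff` from the core), flagged non-core, and excluded
from width measurements; no backbone realism is claimed for turns or loops.

`measure_core_width` reports the maximum within-rung pairwise Cα distance
projected on the cross-sectional plane (nm), linkers excluded. With default
geometry the FapC-like architecture (37-residue rungs, strands 14+13, arcs
5) measures ≈ 4.96 nm and the CsgA-like one (22-residue rungs, strands 9+9,
arcs 2) ≈ 3.06 nm, matching the published ~4.5 nm and ~3 nm fiber-core
widths within their tolerance.

`stack_monomers` continues the rung lattice with pure translations
(`n_rungs × rung_rise` per copy), so the monomer–monomer interface has the
same spacing as internal rungs. `clash_check` reports all non-bonded atom
pairs (sequence separation ≥ 2 within a chain; everything across chains)
closer than 3 Å; default builds are clash-free for repeat lengths 15–60 in
both arrangements, with and without linkers, monomer or trimer. This steric
check is a deliberately coarse stand-in for molecular-dynamics stability
assessment, which is out of scope. PDB output is a CA/pseudo-CB trace, one
chain per monomer, fibril axis +z (stated in a REMARK); round-trips
reproduce coordinates to the format's 1e-3 Å precision.

## Contact-map fulfillment

`contact_distances` minimizes each pair's inter-atom distance over all
monomer copies (fibrils are periodic; the relevant copy pair is the nearest
one). The default contact criterion is pseudo-Cβ within 8 Å, the standard
contact-prediction convention (Cα at a wider cutoff available via the `atom`
argument). A contact to a residue without coordinates (excluded flank) is
flagged missing and counted unfulfilled, never dropped silently.

`fulfillment_report` counts contacts with scaled score > 2.0 and the
fraction of them fulfilled. `classify_contacts` labels a contact `intra` if
fulfilled within one monomer, `inter` if fulfilled only across monomer
copies of the stacked fibril, else `unassigned` — separating intramolecular
from interface covariance. `select_arrangement` picks the candidate
(two-sided vs three-sided) with the highest fulfilled fraction, breaking
ties by clash count and finally by a documented default of `two_sided`,
mirroring the stability outcome for FapC. `annotate_motif_location` flags
whether each CxxC occurrence lies inside the modeled core (strand/arc role)
or outside (linker/flank), testing the observation that FapC's conserved
CxxC sits next to the linkers rather than in the fiber core.

## Synthetic data and what the tests show

All fixtures are generated, with exact planted truth and byte-level
determinism per seed:

* **Operon tables** — per assembly one planted operon (all six components
  with probability `p_full_operon`, else a 2–3-gene negative cluster),
  intergenic gaps uniform on (50, 1500) bp and gene lengths on (300, 1500)
  bp so a second-nearest-neighbor gap never exceeds the 5000 bp threshold;
  Poisson-distributed decoys separated by ≥ 2× the threshold so truth labels
  are unambiguous.
* **Repeat proteins** — repeats from a shared random consensus mutated at
  `sub_rate`, Q/N anchors planted at fixed in-repeat offsets, optional CxxC
  in a linker or strand region, random linkers/flanks (default 20 residues).
* **Potts MSAs** — Gibbs samples from a pairwise Potts model over the 20
  amino-acid states with ferromagnetic couplings `J_ij(a,b) = s·[a=b]` on
  the planted pairs and zero fields. One independent chain per sequence with
  a 1000-sweep burn-in over the coupled sites (chromatic updates: mutually
  non-adjacent sites in one vectorized step); uncoupled sites are exactly
  uniform and drawn directly, so no thinning is needed.

Study conditions used by the headline tests: contact recovery uses L = 60,
N = 1000, 10 disjoint planted pairs at strength 2.0 (10 seeds) and a null of
independent columns at L = 30, N = 300 (20 seeds — the scaled-score tail is
scale-free, so the null size only sets counting resolution). The end-to-end
arrangement experiment uses three 18-residue rungs (L = 54): contacts
harvested from the two-sided model at pseudo-Cβ ≤ 6.5 Å — safely inside the
8 Å fulfillment cutoff so planted contacts are unambiguous — are planted at
strength 1.0 and N = 700; dense topologies at strength 2.0 push the Potts
model into a collectively ordered phase whose transitive correlations
swamp the true edges, so the paramagnetic regime is the scientifically
meaningful recovery setting.

These generators emulate the *statistical* structure of the real inputs,
not their content: no phylogenetic correlation between sequences
(reweighting is exercised only lightly), substitution-only repeat
divergence, uniform amino-acid composition, and contact topologies drawn
from the idealized model itself. Passing tests therefore demonstrate that
each method recovers what it assumes, at realistic sizes — not that real
RefSeq screens or real FapC alignments would behave identically.

## Known limitations

* The screen's "< 5000 bp" rule is interpreted as edge-to-edge distance and
  "four homologs" as four distinct components; both readings are switchable
  but the published analysis did not specify them.
* Repeat detection assumes substitution-style repeat divergence (no indels).
* The solenoid model is a Cα/pseudo-Cβ idealization: no side chains,
  hydrogen bonds, or energetics; turn and loop traces are geometric
  constructs. Width and clash numbers describe this idealization.
* The scaled coevolution score is this package's convention (documented
  above); absolute values are not comparable across scoring programs,
  only the "multiples of average significant signal" reading is.
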