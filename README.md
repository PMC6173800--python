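# fapcore

Sequence and structure analysis of the *Pseudomonas* functional amyloid
(Fap) system, for microbial genomicists and structural bioinformaticians
studying functional amyloids (Fap, curli/CsgA).

Biofilm-forming pseudomonads export amyloid fibers built mainly from FapC,
encoded in the six-gene operon *fapABCDEF*. This package implements the
computational pipeline around that system:

* **Operon screening** — filter homolog hit tables down to genuine *fap*
  operons using the genomic-neighborhood rule (a hit counts when its
  second-nearest *fap*-gene neighbor lies < 5000 bp away within a cluster
  of ≥ 4 distinct components), detect colocalized FapD–FapF pairs, and
  summarise component presence per taxon.
* **Repeat architecture** — detect the imperfect amyloid repeats of
  FapC-like subunits (three ~37-residue repeats; ~22 in CsgA) by
  self-alignment, locate Q/N-X10-Q/N anchor motifs and CxxC sites, and
  assign per-residue strand/arc/linker roles.
* **Coevolution** — predict contacting residue pairs from a deep alignment
  with a pseudolikelihood Potts model (plmDCA-style, 21 states, APC
  correction) plus an MI-APC baseline; scores are reported on an
  average-signal scale where > 2.0 marks strong couplings.
* **β-solenoid modelling** — build idealized Cα/pseudo-Cβ models of the
  fiber core (two-sided or three-sided cross-section, one rung per repeat,
  4.75 Å cross-β stacking), stack monomers into fibrils, measure the core
  width and check sterics.
* **Contact fitting** — score predicted contacts against a model
  (fulfilled = pseudo-Cβ within 8 Å over all symmetry copies), classify
  intra- vs inter-molecular contacts, and select the best-supported
  arrangement.
* **Synthetic data** — deterministic generators with planted ground truth
  (operon tables, repeat proteins, Potts-sampled MSAs) powering all
  parameter-recovery tests.

The model at the core: each sequence repeat forms one rung of a cross-β
solenoid. A rung of length *r* with `n` sides splits into `n` strands joined
by short arcs; strands advance 3.45 Å per residue (pleated so consecutive
Cα are 3.8 Å apart), opposing sheets sit 10 Å apart, and rungs stack at
4.75 Å along the fibril axis. Coupling strengths from the Potts fit,
summarised as APC-corrected Frobenius norms of the 20×20 coupling blocks,
rank candidate contacts which the model must place within the contact
cutoff. See `docs/methods.md` for conventions and parameters.

## Worked example

```python
import fapcore as fc

# a synthetic FapC-like subunit: three 37-residue repeats, 20-residue linkers
seq, truth = fc.gen_repeat_sequence(seed=11, period=37, n_repeats=3,
                                    linker_len=20, sub_rate=0.0)
seg = fc.segment_repeats(seq, expected_period=37)
print(seg.repeats)
# [(21, 57), (78, 114), (135, 171)]

rolemap = fc.assign_roles(seg, "two_sided", arc_length=5)
print(rolemap.strand_lengths())
# [14, 13]

model = fc.build_solenoid(rolemap)
print(round(fc.measure_core_width(model), 2), fc.clash_check(model).count)
# 4.96 0

trimer = fc.stack_monomers(model, 3)
fc.write_pdb(trimer, "fapc_core.pdb")
```

The segmentation recovers the planted repeat boundaries exactly; the
two-sided solenoid built from them has a ~5 nm fiber core — the published
FapC core width of ~4.5 nm within its tolerance, versus ~3 nm for the
narrower CsgA architecture — and no steric clashes. The written PDB holds
three chains (A–C) continuing the 4.75 Å rung lattice.

A command-line interface mirrors the stages:

```
fapcore simulate operons --seed 7 --out sim/
fapcore screen-operons --hits sim/hits.tsv --out screen/
fapcore find-repeats --fasta subunit.fasta --period 37
fapcore couplings --msa homologs.fasta --method plm --out contacts.tsv
fapcore build-model --fasta subunit.fasta --period 37 --monomers 3 --out core.pdb
fapcore fit-contacts --contacts contacts.tsv --model core.pdb
```

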