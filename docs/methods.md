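# Methods

## Retention criteria (QC)

A chain passes sequence QC when all of the following hold; failures are
enumerated, never short-circuited:

1. upstream-reported V-segment length > `min_v_length` (default 250 nt);
2. translation of the assembled variable region, from `frame_offset`,
   contains no stop codon before the end of the junction ("correct reading
   frame" is operationalized as this stop-free translation plus an in-frame
   CDR3 — see 4);
3. nucleotides are strictly A/C/G/T (an N is `ambiguous_nt`; ambiguous
   codons translate to X, not `*`, so an N never masquerades as a stop);
4. CDR3 length is divisible by 3 and its translation equals the reported
   amino acids (`frame` otherwise);
5. the constant-region call resolves to exactly one gene after
   comma-splitting and allele-stripping (`ambiguous_c_call` otherwise);
6. the assembler's `productive` flag is true.

A cell is retained iff it has exactly one passing heavy and one passing
light chain (two passing chains of a type ⇒ `multiplet`) and
`n_genes_expressed ≥ min_genes` (default 500). The stop-codon scan covers
the variable region up to the junction end only: constant-region trailers
are template-switch artifacts in some assemblers and are not the cell's
antibody. Thresholds are configuration values so the pipeline can be reused
on datasets with other conventions.

## Clonal family model

Grouping key: heavy-chain V gene, J gene (allele suffix after `*` stripped;
first gene of multi-calls) and CDR3 amino-acid length. Within a key group,
cells are clustered at fractional CDR3 identity ≥ 0.70, computed
position-wise (Hamming; equal lengths are guaranteed by the key). Identity
is computed on amino acids by default — logos and convergence arguments are
residue-level — with a nucleotide mode available. Single linkage (connected
components of the ≥-threshold graph) is the default realization of
"members assigned at ≥ 70 % identity"; complete linkage is offered for
sensitivity analysis. An epsilon of 1e-9 absorbs floating-point error at
the boundary so a pair at exactly 0.70 merges. Family ids are assigned
after sorting cells by (subject, cell id), making the partition and ids
invariant to input order. Light chains are never a clustering constraint;
per-family light-V concordance is reported as a diagnostic.

A family is convergent (public) iff its members span ≥ 2 subjects. The
persistence table lists, per subject, the blood-draw samples contributing
members, supporting longitudinal clonal-persistence statements.

## Sequence metrics

* Edit distance: unit-cost Levenshtein over full variable-region amino-acid
  sequences (FR1–FR4), the scale on which within-family distances of tens
  of residues arise; computed with edlib. Clustermap ordering uses
  average-linkage hierarchical clustering with label-sorted inputs for
  deterministic ties.
* SHM: position-wise nucleotide mismatch fraction of the observed V segment
  against its aligned germline (IMGT-style percent mutation), N positions
  excluded from numerator and denominator; absent germline yields a missing
  value, never zero.
* Logo PFMs: per-position residue frequencies including an explicit gap
  symbol. Unequal-length sets use a center-gap policy — keep ⌈L/2⌉ residues
  left-anchored and ⌊L/2⌋ right-anchored, gaps inserted centrally — because
  junction conservation concentrates at both CDR3 ends; left/right
  anchoring are also available, and equal-length inputs are policy-
  independent.

## Cell state

CPM = count × 1e6 / total. The marker rule calls plasmablast iff
log2(CPM_PRDM1+1) > log2(CPM_MS4A1+1), unassigned iff both raw counts are
zero; it is scale-invariant per cell. The PCA route log-transforms CPM with
pseudocount 1, selects the top-variance genes (default 500; ties broken by
gene name), centres by gene mean without unit-variance scaling (standard
for log-normalized expression), projects to two components and runs 2-means
with a fixed seed; the cluster with higher mean PRDM1 is labelled
plasmablast. The marker rule is the default because the partition of
interest is anchored to these two genes; the PCA route is confirmatory and
the per-cell discrepancy set is available by comparing the two outputs.

## Epitope mapping

Tiling enumerates k-mers (default 15) at a fixed offset (default 1);
motif scanning is exact substring search with overlaps. Array signals are
projected to residues by the maximum over covering tiles — a single
strongly bound peptide suffices to localize a linear epitope — and
contiguous runs at ≥ 50 % of the profile maximum become candidate
intervals (none when the profile is non-positive; with a flat noisy
baseline and no true signal this fraction-of-max rule is not meaningful,
a known limitation). Global alignment is Needleman–Wunsch with match +1,
mismatch −1, linear gap −2 and a deterministic traceback (diagonal > up >
left); runs of one sequence aligned entirely to gaps in the other are
reported as candidate unique regions (e.g. a homolog-absent loop). The
scheme is deliberately simple and fully stated; affine gaps and
substitution matrices are out of scope. Sequences are used as given — no
implicit signal-peptide trimming (an explicit CLI option trims
N-terminal residues). All coordinates are 0-based, half-open.

## Simulator

The generator emulates the inputs of a plate-based single-cell antibody
discovery experiment with known truth:

* **Germline**: a bundled toy set (12 V ≥ 258 nt and 5 J per locus,
  stop-free random codons, fixed internal seed). No attempt to mirror human
  allele frequencies or SHM hotspots — conclusions about real germline
  usage cannot be drawn from it.
* **Families**: each family is founded by one recombination (random V/J,
  random CDR3 of 10–18 aa, back-translated); founders are rejected if they
  would collide with an existing family's key at ≥ 50 % CDR3 identity, so
  planted families are separable by construction. Members substitute CDR3
  residues per site at `cdr3_intra_family_mutation_rate` (clamped to 0.10
  so expected intra-family identity stays ≥ ~0.8) and V-region nucleotides
  at `shm_rate_per_site` (default 0.02), with substitutions resampled when
  they would create a stop codon so clean cells always pass QC while the
  realized mutation count stays exactly binomial. The CDR3 model is
  substitution-only, preserving length so family members share the
  grouping key by construction; junction indels are outside the model.
* **Cohort**: default 8 subjects × 150 cells, 3 public + 40 private
  families. Public families draw members across subjects (≥ 2 enforced);
  private families belong to one subject; every per-subject budget is
  spent. Isotypes are drawn from `isotype_mix` (default 90 % IgE / 10 %
  IgG, reflecting an IgE-focused sort with occasional switched relatives).
* **Defects**: each class (stop codon, ambiguous nucleotide, short V, low
  gene count, ambiguous constant call, multiplet) is sampled independently
  per cell at its configured rate and recorded in the ground truth. A
  multiplet (second *passing* heavy chain) is only planted in cells whose
  resident heavy passes, since otherwise no second passing chain would
  exist and the planted label could not correspond to an observable
  outcome; the stop codon is placed in the second half of the V segment
  and the N in the first half so co-planted defects remain independently
  visible.
* **Expression**: negative-binomial counts over 1000 genes (size
  r = 1/`nb_dispersion`, default dispersion 0.25 — moderate overdispersion
  typical of deep-coverage plate-based scRNA-seq). Marker means are 5 in
  the low state and 5 × `marker_fold_change` (default 8) in the high state,
  giving the clean PRDM1/MS4A1 separation characteristic of sorted
  plasmablast/memory compartments. Forty additional signature genes (8 vs
  2) emulate the broad plasmablast transcriptional program; without them a
  variance-driven PCA could not plausibly see a two-gene difference, and
  real plasmablasts differ by far more than two genes. A low-gene-count
  defect keeps 300 random genes and zeroes the rest.

One `numpy` generator seeded from `config.seed` drives everything; two runs
with the same config are identical object-for-object and byte-for-byte in
emitted files.

What passing tests on simulated data do **not** show: robustness to
assembler-specific artifacts, real germline diversity, SHM hotspot
clustering, junction indels within families, doublets beyond the
two-passing-chain rule, or batch effects in expression. The peptide-array
simulator is a two-level signal with Gaussian noise; real arrays have
peptide-specific backgrounds.

## Problem sizes and determinism

The shipped checks run the simulator at 300–1200 cells and 12–43 families,
sizes at which family recovery, QC audits and state classification are
already stable (adjusted Rand index ≥ 0.99 at the 1200-cell default).
`scripts/acceptance.py` derives all sub-seeds from its single `--seed`
argument; every quantity it reports is recomputed at run time.
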