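# Methods

`atdqc` implements the computational analyses behind the comparison of two
tRNA-deacylase families: DTD (D-aminoacyl-tRNA deacylase), whose dimeric
active sites receive a cross-subunit Gly-*cis*Pro dipeptide, and its
Animalia-specific paralog ATD, which carries the same dipeptide in *trans*
and thereby gains activity on L-alanine mischarged onto
tRNA-Thr(G4:U69) by eukaryotic alanyl-tRNA synthetase. Four analysis
stages — structural geometry, sequence-family classification,
acceptor-stem wobble scanning, and deacylation kinetics — are glued by a
file-based pipeline, and a synthetic-data module generates inputs with
the statistical and geometric structure each stage assumes.

## Structural geometry

**Torsions.** Backbone dihedrals follow the IUPAC sign convention;
omega(i) is the torsion of the peptide bond *preceding* residue i
(CA(i-1), C(i-1), N(i), CA(i)), so a "Gly-cisPro" call is the omega of
the proline. All angles live on (-180, 180]. A C(i-1)-N(i) distance above
2.5 Å is treated as a chain break and undefines the torsions that span
it; missing backbone atoms undefine the affected angles rather than
raising.

**cis/trans call.** cis iff omega in (-90, +90], trans otherwise — a
symmetric, total rule with a single boundary at ±90°. Published structure
papers rarely state a threshold; this is the conventional midpoint split.

**Motif location.** Every Gly immediately followed by Pro is reported.
The "pocket" of a chain is the best match of the family's motif-1
signature (PQATL for ATD, SQFTL for DTD, one mismatch allowed); a Gly-Pro
is assigned to the chain whose pocket Cα centroid lies nearest its
backbone centroid, and `cross_subunit` records whether that chain differs
from the donor — the defining feature of the DTD-fold dimeric active
site.

**Carbonyl orientation.** The pocket axis runs from the midpoint of the
two carbonyl carbons to the acceptor chain's pocket centroid. The label
is `non-parallel` when the two C=O unit vectors subtend more than the
parallel threshold (default 45°); otherwise `outward-parallel` when their
mean projection on the pocket axis is positive (the DTD chiral filter,
oxygens into the pocket) and `inward-parallel` when negative (the ATD
arrangement). The threshold is exposed because idealized model geometry
needs it: with standard bond lengths/angles a cis peptide cannot bring
the two carbonyls closer than ~51°, so analyses of the idealized cis
dimer use a 60° threshold while real crystal structures, whose geometry
is not ideal, can use the default.

**Superposition.** `kabsch_superpose` is the closed-form least-squares
solution with the reflection excluded by sign correction.
`align_and_superpose` pairs Cα atoms via global sequence alignment
(BLOSUM62, gap open -11/extend -1; chains matched greedily by alignment
score), then iterates superposition with pruning of pairs deviating more
than 3.5 Å until the pair set is stable; if pruning would leave fewer
than three pairs the unpruned solution is reported. Published r.m.s.d.
values for distant homologs are tool-dependent, so this protocol matches
them within tolerance rather than bit-exactly.

**Rigidity.** The motif's mean backbone B-factor is expressed as a
z-score against all backbone atoms of the donor chain; negative values
mean the motif is more ordered than its chain. A uniform-B structure
yields z = 0; all-zero B-factors (absent data) raise.

**Contacts.** Side-chain heavy atoms of a probe residue within 3.5 Å of
the motif backbone (N/CA/C/O), with a same-chain flag — the conserved
arginine in DTD clamps the motif from the same monomer, ATD's migrated
arginine from the dimeric counterpart.

Waters and heteroatoms are parsed but flagged and excluded from all
geometry. For alternate conformations the highest-occupancy altloc wins,
ties broken by altloc letter.

## Family classification

Signature motifs: ATD `PQATL` and `TNGPYTH`; DTD `SQFTL` and `N.GPVT`
(`.` any residue; the literature writes NxGPVT). Matching allows one
mismatch by default, and the score is the count of ATD patterns with a
best hit at ≤1 mismatch minus the DTD count; the sign calls the family,
zero is `unknown`. Pairwise identity comes from a global BLOSUM62
alignment with affine gaps; the denominator is alignment columns after
trimming terminal overhangs, since the published "<30% identity" figure
does not specify a convention. Anchor residues (DTD Arg7; ATD Gln16 and
Arg151) are read off an alignment to bundled reference sequences; the
bundled references are *synthetic* constructs carrying the motifs and
anchors at the canonical positions, and real family representatives can
be substituted via the `reference` argument or CLI flags.

## Acceptor-stem wobble scanning

Mature tRNA gene sequences (T normalized to U) are numbered canonically:
a terminal CCA, if present, is stripped; the final remaining base is the
unpaired discriminator (position 73 in a 73-nt gene); acceptor-stem pair
i joins positions i and 73-i for i = 1..7. A dot-bracket secondary
structure, when supplied, overrides positional pairing. G4:U69 is
directional — G on the 5' strand, U on the 3' strand; the reversed
U4:G69 is counted separately. The score filter is strictly greater than
50 bits (tRNAscan-SE), matching the stated retrieval criterion.
Enrichment counts isodecoder duplicates per gene copy, an explicit choice
where the published percentages do not say. Co-occurrence between
per-organism tRNA-Thr(G4:U69) enrichment (threshold 10% — the published
enrichment range is 20-40%, background isotypes sit near 0-5%, so any
cutoff between those bands gives the same dichotomy) and ATD presence is
summarized by a 2x2 table, diagonal concordance, and a two-sided Fisher
exact p computed by full hypergeometric enumeration.

## Kinetics

Deacylation time courses are fit to S(t) = S0 exp(-k t) by bounded
nonlinear least squares (k ≥ 0, S0 in (0, 1.2]), initialized from a
log-linear regression on the positive fractions; no plateau term is
included, matching the stated assay model. "The enzyme acts at X nM" is
operationalized as final-timepoint depletion of at least 50% (a
configurable threshold); the discrimination factor is the ratio of
minimal effective concentrations (cognate over non-cognate), and the
EF-Tu protection factor is the fold-shift in minimal effective
concentration with versus without EF-Tu.

## Synthetic data: what it emulates, and what it does not

* `build_peptide` constructs chains from per-residue (phi, psi, omega)
  by natural-extension (NeRF) placement using a fixed ideal-geometry
  table (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, C=O 1.231 Å; angles
  C-N-CA 121.7°, N-CA-C 111.2°, CA-C-N 116.2°, CA-C-O 120.8°). The exact
  values matter only for round-trip stability (torsions rebuild to well
  below 1e-6°), not for any biological claim.
* `build_deacylase_dimer` arranges two copies of the family reference
  sequence, built as a regular helix with the family's motif torsions
  (trans for ATD, cis for DTD, psi flipped ~180° between them), into a
  C2 dimer whose Gly-Pro centroid coincides with the partner's pocket
  centroid, offset a few Å along the carbonyl direction (toward the
  carbonyls for the cis fold, away for the trans fold). It reproduces
  the *topology* of the cross-subunit site — not a real fold: there is
  no tertiary packing, and the cis-carbonyl parallelism floor noted
  above applies. Motif backbone B-factors are set low against a
  modulated chain baseline, so rigidity z-scores are negative by
  construction.
* `gen_family_sequences` embeds the signature motifs at offsets 30 and
  100 in uniform-random background; mutations hit the background at the
  given rate and each motif at most `max_motif_mismatch` times, so the
  signature stays detectable by design.
* `gen_trna_set` produces 73-nt genes with a Watson-Crick acceptor stem
  except for pair 4, which is G4:U69 with the isotype's probability; the
  body between the stem halves is random filler (no D/T/anticodon arm
  realism — out of scope by design). Default study settings: Thr 30%,
  Cys 5%, matching the published enrichment averages.
* `gen_decay_series` / `gen_dose_ladder` produce exponential decays with
  Gaussian noise clipped to [0, 1.2]; the dose ladder scales k linearly
  with enzyme concentration (k = k_eff · c), with an optional uniform
  protection divisor for EF-Tu. Default k_eff values place the
  non-cognate substrate's minimal effective concentration at 1 nM and
  the cognate's at 50 nM on the ladder 0.2-5000 nM, i.e. the reported
  assay conditions; activated EF-Tu protection is 100x for the cognate
  and 50x for the non-cognate substrate.
* `gen_presence_table` assigns each organism an enrichment state, draws
  its G4:U69 gene count binomially, and sets ATD presence to agree with
  the *realized* enrichment with the stated concordance.

Every generator draws from its own independent, seeded stream
(`SeedSequence([seed, stream_id])`), so outputs are bit-reproducible and
adding a generator never perturbs existing fixtures.

Passing tests on these inputs demonstrate that the *procedures* are
correct (torsion recovery, classification logic, counting, fitting,
exact tests), not that real crystal structures or genomes behave
identically; the published r.m.s.d./identity/residue-count figures for
the deposited ATD and DTD entries, and the GtRNAdb enrichment
percentages (human Thr ~20%, Cys ~3.4%), are database/deposition-
dependent and are verified as documented smoke checks against the real
files when those are available, not as CI assertions.

## Numerical choices and degenerate inputs

* Torsion range (-180, 180]; -180 reports as +180. Degenerate
  (coincident/collinear) point sets raise rather than return garbage.
* Superposition needs ≥3 non-collinear pairs; collinearity is detected
  from the second singular value.
* Fisher enumeration compares table probabilities with a 1e-9 relative
  tie tolerance, the standard guard for float pmf ties.
* Decay fits cap optimizer evaluations (default 2000) and return the
  best estimate flagged `converged=False` on failure.
* Problem sizes in tests and the acceptance script (500-replicate fit
  recovery, 200-500-gene tRNA sets, 24-organism presence tables,
  20-replicate superposition noise checks) were chosen as the smallest
  sizes at which the binomial/CLT intervals being asserted are
  meaningfully narrow.

## Known limitations

* The synthetic dimer is a topological stand-in; superposing the ATD
  against the DTD stand-in does not reproduce the published 1.68 Å/141
  Cα figure, which requires the deposited coordinate files.
* Sequence classification is motif-based, not profile-based; remote
  homologs with degraded motifs return `unknown` rather than a forced
  call.
* Acceptor-stem reconstruction is positional (or dot-bracket-driven);
  genes with unremoved introns or non-canonical stem lengths need the
  secondary-structure override.
* The EF-Tu protection model is a uniform rate divisor — no binding
  thermodynamics are modelled.
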