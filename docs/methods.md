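# Methods

This note documents the models, conventions and numerical choices behind
aquamip, and what its synthetic-data verification does and does not
establish about real data.

## Sequence model and coordinate conventions

Proteins are validated at load: 20 canonical residues, upper-cased, one
trailing `*` stripped; records with ambiguity codes (B/J/O/U/X/Z) are
rejected individually so one bad record never aborts a run.  GFF3 is
1-based inclusive on disk; all internal coordinates are 0-based
half-open; reports print 1-based residue positions.  Splice variants are
independent records sharing a `gene_id`.

## Physicochemical profile

- **GRAVY** is the arithmetic mean of Kyte–Doolittle hydropathy values
  (scale as shipped with Biopython).
- **MW** sums average-isotopic residue masses plus one water
  (Biopython's ProtParam machinery), reported in kD to two decimals.
- **pI** is found by bisection on the Henderson–Hasselbalch net charge
  over the ionisable side chains D, E, C, Y, K, R, H plus the free
  termini.  The charge curve is strictly decreasing in pH, so bisection
  on [0, 14] converges; iteration stops at |charge| < 1e-4 (cap 200
  iterations).  Two named pKa sets ship (`expasy` default, `emboss`
  alternative), each a simplified set with single terminal pKas.  This
  is deliberately *not* the residue-context Bjellqvist model used by
  some web tools; values typically agree to a few tenths of a pH unit
  but are not identical, which is why the package verifies pI against a
  brute-force grid scan of its own charge function rather than against
  external predictions.
- **TM segmentation** is a centred sliding-window hydropathy rule:
  window 19 residues, threshold 1.6, minimum segment length 15, merge
  gap 4.  Maximal runs of qualifying window centres become segments.
  This approximates, but does not reproduce, HMM-based topology
  predictors; TM counts are indicative and are not used as acceptance
  quantities anywhere.

## NPA boxes and the silicon rule

Detection scans for `first`-`P`-`third` with `first = [NS]` (the Ser
option catches XIP-type SPI/SPA boxes) and `third = [ASTVLIC]`, covering
the observed family variants NPA/NPS/NPV/NPT/NPL plus Cys as a
conservative extension; both alphabets are configurable.  With more
than two candidate triplets, the pair maximising a positional
plausibility score wins: one point each for a first box in the first
sequence half and a second box in the second half, minus the distance of
the implied spacing from the canonical 90–130 band divided by 50; ties
break to the leftmost pair.  Zero matches flag the record
`truncated_or_atypical` and route it to the exclusions list, matching
the field convention of excluding NPA-less fragments from family tables.

**Spacing convention.** Spacing is the number of residues strictly
between the two triplets, `start(LE) − start(LB) − 3`.  Published
surveys rarely print their counting rule; this convention is declared in
every report header.  The silicon call is: GSGR ar/R filter and spacing
108 → `canonical_108`; GSGR and spacing 107 or 109 → `variant_spacing`
(known silicon accumulators deviate by one residue); anything else,
including a missing filter, → `not_si_type`.

## Residue projection (ar/R, Froger)

Marked sites are columns of a labelled reference alignment, not offsets
from the NPA boxes, because truncated isoforms break offset arithmetic.
A query is aligned to the best-scoring panel member (global, BLOSUM62,
affine 10/1, free end gaps) and the marked columns are projected through
the alignment; a column where the best member is gapped falls back to
the next-best non-gapped member; projections onto query gaps report "/".
Projections are refused (all-"/" with a reason) below a raw alignment
score of 50, which cleanly separates MIP-like queries (scores in the
hundreds) from unrelated sequences (scores near 10).

## Classification

Queries are threaded into the panel alignment through the best-member
pairwise alignment (query insertions relative to that member are
dropped, as in profile threading); a full de-novo progressive MSA is
intentionally not performed — `build_distance_matrix` accepts any
user-supplied alignment when one is preferred.  Distances are
p-distances with pairwise deletion of gap columns.  Neighbor joining is
the standard Saitou–Nei algorithm with two declared determinism rules:
ties in Q break to the lexicographically smallest index pair, and
negative branch lengths are clamped to zero.  On additive matrices the
generating tree is recovered exactly (verified to 1e-9).  The subfamily
is the majority label of the query's sister group; bootstrap support
resamples alignment columns (default off in the library; the CLI
default is 100 replicates, chosen for desk-scale runtime — raise it for
publication figures).  Support below 0.7 flags `low_support`.

PIP1 vs PIP2 uses the N-terminal tail length before the first predicted
TM helix, with the cutoff calibrated as the midpoint of the panel's
PIP1 and PIP2 mean tail lengths; a tail exactly at the cutoff is PIP2
by declared tie-break (flagged), and absent TM segments fall back to the
nearest-reference subgroup.

## Promoter scanning

Promoters (2 kb upstream by convention) are scanned at every position on
both strands under IUPAC set semantics; `N` in the promoter matches
nothing; all overlapping matches are counted, including self-overlaps —
declared in the report header because overlap policy materially changes
counts.  The packaged motif table is a curated approximation of nine
commonly cited stress/hormone/light elements (ABRE, ARE, G-box,
CGTCA-motif, LTR, MBS, TCA-element, TC-rich repeats, TGA-element);
absolute counts depend on the consensus table used and are therefore
never treated as reproduction targets — users comparing against a
specific database should load that database's strings.

## Expression utilities

`log2(FPKM+1)` transforms, Pearson co-expression pairs above a strict
threshold (zero-variance genes excluded with a warning; at least three
samples required), abundance shares (subset FPKM over total FPKM), and
DE flagging as |log2 FC| ≥ log2(2) with raw p ≤ 0.05 and BH FDR ≤ 0.05
(statsmodels' step-up, verified against a by-hand implementation).  The
count-based negative-binomial DE test is out of scope: p-values are
inputs, and the provided two-group Welch t-test on log2(FPKM+1) is a
labelled convenience, not an equivalent.  Heat-map row normalisation is
per-gene z-scoring of log2(FPKM+1), a declared choice.

## Synthetic data: what it emulates and what it does not

The protein generator renders the canonical MIP architecture: six 23-aa
TM helices drawn from a strongly hydrophobic pool (I/L/V/F) joined by
polar loops, the two boxes in loops B and E, ar/R sites on helices 2/5
and loop E, Froger sites in loop C, loop E and the C-tail.  Loop lengths
were fixed so that any inter-box spacing from 90 (the architectural
minimum) upward is constructible by resizing the post-LB loop.  Nine
invented subfamily templates (PIP1/PIP2, TIP1/TIP2, NIP1/NIP2,
SIP1/SIP2, XIP1) carry the subfamily-typical marker residues — e.g.
F-H-T-R + (Q)S-A-F-W for PIPs, the GSGR/108 silicon signature for NIP2,
SPI/SPA boxes for XIP — with within-subgroup members at ~8% divergence.
Noise is substitution-only and class-preserving (TM positions stay
hydrophobic, loops stay polar) so planted coordinates remain
addressable; accidental NPA-like triplets are deterministically
repaired, and decoy triplets can be planted in the tails on request.
One user seed fans out to per-object child seeds by CRC32 of object
tags, so adding an object never perturbs the others.

The promoter generator rejection-screens its random background against
the planted consensi (both strands) so planted offsets are the complete
hit set; the FPKM generator plants pairs as scaled copies plus Gaussian
noise calibrated to a target correlation and rejection-screens the
background so no unplanted pair exceeds r = 0.6 (log-normal profiles are
heavy-tailed, and chance correlations at 12 samples are otherwise not
negligible); the gene-model generator writes valid GFF3 with a specified
intron-count distribution over 1–4 introns and optional UTR-less
transcripts.

What passing these closures shows: each analysis stage inverts its
generator exactly under realistic geometry and noise.  What it does not
show: performance on real proteomes, where divergence includes indels,
compositional bias, genuinely atypical architectures and annotation
errors; where TM hydropathy contrast is weaker; and where the reference
panel's coverage, not the algorithm, limits projection quality.  The
packaged panel is synthetic and clearly labelled as such — production
runs should substitute a curated alignment of experimentally
characterised MIPs (the file formats are documented and identical).

## Verification problem sizes

The acceptance script and suite use: 100 random sequences for the pI
grid oracle (grid step 1e-4 pH); 500 seeded proteins for NPA recovery
(spacing uniform on 90–130, 5% mutation), with decoys in a second run of
500; the full 16-member panel for identity projection; 200 queries at
5–20% mutation for classification accuracy (no bootstrap, for runtime);
25 random additive matrices of 4–8 taxa for NJ; 20 promoters and 10
FPKM matrices for the planted-count loops; and a 33-transcript gene-model
set with intron distribution {1:3, 2:17, 3:10, 4:3}, the shape observed
in a typical dicot aquaporin family.

## Known limitations

TM counts from hydropathy segmentation disagree with HMM predictors on
marginal helices.  The simplified pKa model shifts pI slightly relative
to residue-context models.  p-distance NJ can misplace queries at
extreme divergence where model-corrected distances would not.  Promoter
counts are consensus-table-dependent.  Naming of new members
(`PIP2;4`-style ordinals) follows genomic position only when a GFF3 is
supplied, otherwise input order.
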