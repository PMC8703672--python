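# Methods

## The problem

ITS2 secondary structure is a workhorse of species delimitation in groups
whose morphology is too plain to separate taxa, such as *Chlorella*-like
coccoid green algae. The spacer folds into four helices (I–IV) around a
ring of five single-stranded regions; because the structure is conserved
while the sequence drifts, structurally homologous base pairs can be
compared across taxa. Compensatory base changes (CBCs, both partners
substituted with pairing preserved) and hemi-CBCs (one partner substituted)
in the conserved parts of the molecule are treated as markers that often
accompany speciation, and a numeric encoding of the conserved pairs — the
barcode — summarises each taxon as a short integer vector whose distinct
values define ribotypes. This package implements that analysis end to end,
together with the *p*-distance divergence stage that usually accompanies
it.

## Secondary-structure model

The folder maximises a simple additive score over pseudoknot-free
structures: pair weights GC/CG = 3, AU/UA = 2, G·U/U·G = 1, a +1 bonus for
each pair stacked directly on another, and a minimum hairpin loop of 3
unpaired bases (so a pair (i, j) requires j − i ≥ 4). This is a
Nussinov-style dynamic program, not a nearest-neighbour free-energy model:
it reproduces clean stem-loop layouts and is exactly optimal under its own
scoring (verified against exhaustive enumeration for lengths ≤ 12), but it
will not reproduce a thermodynamic folder's output base for base. For
published-quality ITS2 models the supported route is to import structures
computed by an external folding server as Vienna dot-bracket triplets
(`fold --import-vienna`); the built-in folder keeps the pipeline
self-contained and testable.

Determinism: among equal-score structures the folder returns the one whose
sorted pair list is lexicographically smallest. Because all pair weights
are positive, no optimal structure's pair list is a prefix of another's,
which makes the greedy "smallest first pair, then minimise inside, then
minimise to the right" traceback exact. Constraints (forced and forbidden
pairs) restrict the DP's state space, so forcing a pair can never increase
the optimal score; inconsistent constraints (crossing pairs, non-pairing
bases, loop violations) are rejected up front.

### Helix annotation

Pairs are chained into stems; stems separated by internal loops or bulges
of at most 3 unpaired bases on either strand (configurable
`merge_tolerance`) merge into one helix. The four largest top-level stems
are labelled I–IV in 5′→3′ order, each helix owning its whole span from
basal 5′ to basal 3′ position — hairpin loop and tolerated internal loops
included — and the single-stranded regions are the maximal top-level
unpaired intervals. With this convention the canonical model has exactly
four helices and five single-stranded regions (leading tail, three
inter-helix linkers, trailing tail); models that deviate are returned
flagged non-canonical rather than rejected. Coordinates are 1-based
everywhere, and a pair's helix-local address is (helix label, offset from
the basal pair), so "helix III, offset 1" is the basal pair of helix III.

## Barcoding and event classification

The pair-code legend (1–8, above) is fixed. Coding is template-driven: a
template slot anchors a pair on a reference structure; a query's residues
at the mapped positions are coded 1–6 when the query's own structure pairs
them, 7 when paired but non-complementary, and 8 when either side is
gapped, deleted or left unpaired by the query structure. Ambiguity (N) at
a slot codes 7 against a concrete partner and 8 against another N — a
conservative choice, since an N can never confirm a compensatory change.
Mapping a query onto the reference uses the package's global aligner
unless a pre-made alignment (or identity coordinates) is supplied.

Event classification operates on nucleotide identity, not code identity:
with both codes in 1–6, two changed nucleotides are a CBC (so U-A → A-U is
a CBC), one is an hCBC, zero is no event; transitions from 1–6 to 7/8 are
pairing losses, the reverse are gains, and 7/8 → 7/8 is silent. Swapping
the operands maps loss ↔ gain and fixes every other kind, which is what
makes comparison reports direction-independent.

The membership of the conserved slot set is a property of the template,
not of the code: templates are TSV inputs (slot, 5′ anchor, 3′ anchor,
conserved flag), because published conserved-position lists are inherited
from earlier genus-level work and shown graphically rather than printed.
The synthetic generator's template flags the basal five pairs of each
helix conserved; a user reconstructing a published genus template loads it
the same way.

## Distances

*p*-distance = differing / compared sites under pairwise deletion (columns
with a gap or N in either row are dropped; complete deletion is available
by flag). The standard error is either the analytic binomial form
√(p(1−p)/n) or a seeded bootstrap; the default for published-style tables
is bootstrap with 1000 replicates, matching common practice in distance
software. The bootstrap resamples the n compared columns with replacement
— since a pairwise comparison reduces to n exchangeable columns of which a
fraction p differ, this is binomial resampling of the difference count —
and reports the standard deviation (ddof = 1) of the replicate estimates.
Between-species entries are arithmetic means over all cross-species strain
pairs ("between group mean distance"); their SE is computed on the
concatenated comparison (total differences over total compared sites),
which coincides with the per-pair SE when strains within a species are
identical. The published table layout (distances below the diagonal, SEs
above, blank diagonal, 4 decimals) is written by
`seqio.write_distance_matrix(..., layout="lower-with-SE-upper")`.

The bundled Gotoh aligner (match +1, mismatch −1, gap open −4, gap extend
−1; a gap of length k costs open + k·extend) exists only so the pipeline
runs without a curated alignment; real studies align ITS manually, and a
supplied alignment always takes precedence.

## Synthetic data: what it emulates, and what it does not

`make_reference` designs a sequence whose intended structure has stems of
12/8/20/10 pairs, hairpin loops of 3 nt and five single-stranded regions
of 2 nt — 122 nt with 100 paired nucleotides (82.0%), matching the paired
fraction reported for real ITS2 in the group this generator emulates.
Helix pairs are sampled GC/CG with probability 0.55, wobble with 0.10,
A-U/U-A otherwise. The geometry prioritises the observed paired fraction
over total length; a real ITS2 of ~230 nt with the same paired fraction
would need proportionally longer stems.

Planted events substitute partners uniformly among the qualifying options
(CBC: legal pair with both bases changed; hCBC: legal pair with one base
changed; pairing loss: one partner broken, and the pair removed from the
mutant's structure). Background divergence is placed by quota — exactly
round(d × unmasked sites) substitutions outside the template anchors — so
the realized divergence equals the target with zero variance and recovery
tests have exact expectations; an i.i.d. per-site mode is available by
flag for statistical checks. The substitution model is uniform over
alternatives with no transition/transversion bias, no rate heterogeneity
and no indel evolution beyond the planted events; passing recovery tests
therefore demonstrates the pipeline's correctness in a noise-free regime,
not its robustness to alignment error or homology misjudgement, which in
real studies is resolved by eye. The default study design is two species:
species 1 with three strains and two ribotypes (a pairing-loss variant at
a non-conserved slot in one strain), species 2 separated by one conserved
basal-helix-III hCBC plus one hCBC and one CBC in the variable apical part
of helix I and 10% background divergence.

Problem sizes in the validation suite — 200 sequences of length ≤ 12 for
the enumeration oracle, 500 mutants for event recovery, n = 700 sites and
1000 bootstrap replicates for the divergence stage — keep every check
exhaustive or tightly converged while completing in seconds.

## Numerical and interface choices

- All internal computation is in the RNA alphabet; T is accepted on input,
  recorded, and restored on output. FASTA output wraps at 70 columns.
- Validation errors name the offending line; the CLI maps them to exit
  code 2 and writes a provenance JSON (inputs, parameters, version) beside
  every output, with no timestamps so reruns are byte-identical.
- Helix I homology in the variable apical region is not adjudicated: the
  template's conserved flags decide which slots count, and the package
  reports variable-region events separately instead of attempting a manual
  homology call.
- Delimitation output is deliberately descriptive ("differentiated at
  conserved positions: yes/no", ribotype counts); CBC/hCBC presence
  supports a species hypothesis but is not used as an automatic species
  test.

## Known limitations

The folder's scoring is not thermodynamic; the aligner is pairwise only
(no multiple alignment); distances are uncorrected (no JC/K2P); no tree
inference or support values; ribotype labels are internal to a run and do
not reproduce labels assigned in earlier published schemes; GenBank
fetching is out of scope — accession FASTA files are supplied by the user.
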