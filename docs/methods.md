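# Methods

## Model

`pocketcons` treats pocket conservation as a count-enrichment problem. Let
TA be the number of heavy atoms of the protein, PA<sub>i</sub> the number of
atoms lining pocket *i*, and TCA<sub>j</sub> the number of heavy atoms
belonging to residues conserved in the alignment prefix that contains the
query plus its *j* closest homologs (rows ordered by increasing e-value).
If conserved atoms were spread uniformly over the protein surface and
interior, a pocket would be expected to contain
EPC<sub>ij</sub> = TCA<sub>j</sub> · PA<sub>i</sub> / TA conserved atoms.
The observed count OPC<sub>ij</sub> is compared to this expectation through
the Poisson point probability

p<sub>ij</sub> = e<sup>−EPC<sub>ij</sub></sup> · EPC<sub>ij</sub><sup>OPC<sub>ij</sub></sup> / OPC<sub>ij</sub>!

evaluated in log space (via `scipy.special.gammaln`) for numerical
stability. The point probability — not a tail probability — is the printed
statistic; `tail=True` switches every scoring entry point to the upper-tail
P(X ≥ OPC) for users who prefer a proper exceedance probability. Note the
point probability is small both under enrichment and under depletion, which
is why the classifier below also requires OPC/EPC > 1.

Assumptions worth stating: conserved-atom placement under the null is
uniform over all heavy atoms (no burial or surface correction); pockets are
scored independently (no multiple-testing correction — α = 0.05 applies to
raw p-values); atoms shared by overlapping pockets count once per pocket.

## Conservation rule

A column is conserved when the query's residue is non-gap, is the modal
residue of the column, and its frequency over **all** rows (gaps count in
the denominator and never match) reaches the identity threshold. The
threshold starts at 1.0; when no column qualifies it is lowered in steps of
0.05 to a floor of 0.50, stopping at the first threshold with at least one
qualifying column. The schedule is applied independently per prefix depth.
All three constants are configurable; the step/floor values are a
determinism choice, since only the "100%, lowered when empty" behaviour is
fundamental. Requiring agreement with the query is what lets a column be
attributed to a specific residue of the scored structure; for homodimers,
every chain whose sequence matches the ungapped query contributes its
residues to the conserved set (and its atoms to TCA).

## Depth optimization

For each depth *j* in [2, N] the package builds the conservation profile,
scores every pocket, and records the objective: the minimum p-value over
*enriched* pockets (+∞ if none). The chosen depth *j\** is the argmin, ties
broken toward the smallest *j* (fewest sequences). Restricting the
objective to enriched pockets prevents the optimizer from chasing depleted
pockets, whose point probability is also small; `objective_mode="all"`
exposes the unrestricted variant. A `strict_depth_range` flag narrows the
scan to [2, N−2] for compatibility with conventions that exclude the
full-alignment prefix; the default includes it, as there is no statistical
reason to discard the deepest prefixes. At *j\**, conserved pockets are
those with OPC/EPC > 1 and p < α; the lowest-p conserved pocket is the
predicted active site. When no depth yields any enriched pocket the result
carries `active_site_pocket=None` and a warning — typical of degenerate
inputs where every residue is conserved (then EPC = PA = OPC and the ratio
is exactly 1).

Alignment preprocessing: `max_seqs` (default 50) truncates the ordered
alignment before optimization; an optional greedy redundancy filter drops
any homolog with ≥ 70% identity (identity = matches / co-aligned non-gap
columns) to an already-kept row, keeping the query and preserving e-value
order. The greedy keep-first scan replaces clustering-based redundancy
removal: it is deterministic, order-respecting, and guarantees the same
all-pairs < 70% property.

## Composite sites

Active sites are frequently composite — a catalytic pocket flanked by
pockets that complete the substrate-contact surface. Two pockets are
contiguous when they share a lining residue or their closest heavy atoms
are within 4.5 Å (≈ van der Waals contact; configurable, since contiguity
has no canonical definition). Starting from the active-site pocket, the
composite grows by repeatedly adding conserved pockets adjacent to the
current composite, scanning in order of increasing p-value, until a fixed
point; non-conserved pockets never bridge. The result equals the connected
component of the seed in the conserved-pocket adjacency graph, and is
monotone in the distance cutoff.

## Composition statistics

Composition is atom-based: atoms of each amino-acid type (or atom type)
lining the pockets of a group, divided by the group's total atom count.
Atom types key main-chain atoms (N, CA, C, O, OXT) by bare name and
side-chain atoms as `<aa>:<name>` (e.g. `W:NE1`, `Y:OH`), so chemically
distinct donors/acceptors stay separate. The conserved and non-conserved
groups partition all pockets by default: pockets that are enriched but not
significant are assigned to non-conserved, so the "all" table is exactly
the atom-weighted mixture of the two groups; `strict=True` instead leaves
those in-between pockets out of both groups, matching the literal
definitions (ratio > 1 and p < α vs ratio < 1 or p > α). Group differences
are tested per amino acid with a one-way ANOVA whose observations are
per-protein fractions (one vector per protein per group), since pockets of
one protein are not independent; a per-pocket mode is available through the
same functions by passing single-pocket runs.

The PROSITE baseline pools the literal (completely conserved) residues of
each pattern — classes, negations and wildcards contribute nothing;
repeats on literals expand the multiset, and bounded repeats like `T(2,4)`
count their guaranteed minimum. Patterns whose literals are all cysteine
are excluded so that disulfide-scaffold motifs do not dominate; pooling is
at residue level (a pattern with three literal glycines contributes three).

## Synthetic study conditions

The generator emulates the statistical structure of a conservation
benchmark without any downloads. Defaults, used by the tests and the
acceptance script: 150 residues, 5 disjoint pockets of 8 residues
(windows evenly spaced along the chain; pocket atoms are all atoms of the
member residues), 30 homologs, per-site substitution probability
min(k·0.03, 1) for homolog k, divergence breakpoint 30. Residue types are
drawn uniformly from the 20 standard amino acids; structures use correct
per-residue heavy-atom complements with coordinates on a coarse helix
(radius 2.3 Å, 100° twist, 1.5 Å rise) plus sub-angstrom jitter. The
planted pocket's residues stay fixed up to the breakpoint and mutate at
the background rate beyond; alignments are gap-free, which keeps the
column→residue map trivial and isolates the scoring logic (gap handling is
unit-tested separately). The rate/breakpoint defaults make the planted
signal strong while decoys still acquire occasional conserved columns at
shallow depths — with 30 homologs at rate 0.03 a background column is
fully conserved at depth 2 with probability ≈ 0.91, and essentially never
by depth 15.

What passing the synthetic benchmark does **not** show: performance on real
proteins, where pockets overlap, alignments have gaps and fragments,
conservation is graded rather than switch-like, and e-value ordering only
approximates evolutionary distance. The generator validates the machinery
(bookkeeping, optimization, classification), not field accuracy.

Problem sizes in the shipped tests and acceptance script — 100 replicates
of the default conditions, 50 optimizer-oracle instances, 20-fixture
property sweeps — were chosen so the whole suite completes in seconds while
keeping Monte-Carlo estimates stable at the asserted thresholds.

## Numerical and degenerate-input choices

- Poisson: EPC = 0 gives p = 1 for OPC = 0 and p = 0 otherwise; negative
  inputs are rejected.
- Ratio: OPC/EPC, 0 when OPC = 0, NaN when EPC = 0 (a pocket can then never
  be enriched).
- Threshold comparisons use a 1e−9 slack so accumulated floating-point
  error in the 0.05 schedule cannot skip a threshold.
- Tie-breaks are total and deterministic: depth ties → smallest j; pocket
  p-value ties → lexicographic pocket id; size ties in the largest-pocket
  predictors → lowest p (conserved variant) or smallest id.
- PDB reading keeps the first-listed altLoc conformer per atom, drops
  hydrogens/waters/HETATM, and types non-standard residues as `'X'` (they
  count toward TA but can never be conserved, since `'X'` never equals an
  alignment residue of the query). MSE and other modified residues are
  therefore excluded from conservation — a deliberately conservative
  choice.
- Pocket "size" is solvent-accessible volume when the input provides it,
  else the lining-atom count.

## Known limitations

- No multiple-testing correction across pockets; α is per pocket.
- The uniform-spread null ignores that pockets are surface features while
  TA counts buried atoms too, which inflates enrichment for any surface
  patch; comparisons *between* pockets are unaffected.
- Redundancy filtering is greedy, not optimal set cover.
- mmCIF input, pocket detection itself, alignment building and volume
  computation are out of scope; pockets and alignments are consumed as
  produced by upstream tools.
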