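# Methods

## Problem setting

Given contigs 𝒞 (a prior, fragmented assembly) and long reads ℒ (HiFi-like:
long, low-error), produce scaffolds: disjoint subsets of 𝒞, each an ordered
sequence of contigs used in direct or reverse-complemented form, with every
consecutive pair linked by at least one long read. Two competing objectives
drive the design: recall (as few, long scaffolds as possible) and precision
(the order/orientation within each scaffold matches the unknown genome).

## Sketch-based end mapping

Subjects are summarized by minhash sketches of their canonical
(w,k)-minimizer sets; queries are the two ℓ-bp ends of each read (a single
whole-read sketch when the read is shorter than ℓ). For trial
t ∈ [0,T), sketch[t] = min over the set of a salted 64-bit splitmix hash;
the per-slot agreement rate between two sketches is an unbiased estimator of
the Jaccard similarity of the underlying sets (verified to within
3·√(J(1−J)/T) in the test surface). Restricting queries to read ends keeps
the two ground sets comparable in size, and lets one read link two contigs
that are distant in read coordinates but adjacent on the genome.

Parameters, defaults and rationale:

| parameter | default | meaning / why |
|---|---|---|
| k | 15 | minimizer k-mer length; 15-mers are effectively unique at these genome sizes |
| w | 10 | window (in k-mers); density ≈ 2/(w+1) → ~360 minimizers per 2 kb end |
| T | 30 | minhash trials (sketch size); similarity resolution 1/30 |
| ℓ (end_len) | 2000 bp | read-end length sketched |
| tau | 0.02 | minimum similarity reported; below 1/T, i.e. any nonzero agreement |
| top_n | 3 | subjects reported per end, ranked by similarity then id |
| salt | 42 | seed of the T hash functions; fixed constants, platform-independent |

tau deserves a note. Unrelated minimizer sets share no elements, so their
sketch agreement is zero up to ~2⁻⁶⁴ hash collisions — there is no noise
floor to stay above. The informative mappings for scaffolding are precisely
the *weak* ones: a read end straddling the sequencing gap between two
contigs overlaps each by only a few hundred bp (Jaccard ≈ 0.05–0.15 against
a 5 kb contig), and reporting both such subjects is what lets a single read
witness three consecutive contigs. Those three-contig mappings populate the
link-set intersections the wiring heuristic maximizes; a conservative tau
(≥ 0.2) silences them and degrades every read to at most two subjects, which
makes all wiring intersections empty. With top_n = 1 the mapper reproduces
the strict one-subject-per-end regime.

Multi-mapping is capped per end (top_n), ties broken by subject id; subjects
shorter than k+w−1 are unsketchable and never matched.

## Contig graph

Mapping tuples are grouped by read; each unordered pair of distinct contigs
in a read's mapped set contributes the read id to that pair's link set (a
read counts at most once per edge; both ends on one contig create no edge).
Vertices include unmapped contigs, which later pass through as singleton
scaffolds. The total support identity Σₑ|Lₑ| = Σᵣ C(#contigs(r), 2) is an
invariant of construction. A `min_support` filter is available but defaults
to 1 (off).

## Wiring and path enumeration

Each vertex of degree ≥ 2 wires the pair of incident edges maximizing
|Lᵢ ∩ Lⱼ|; ties prefer the larger |Lᵢ|+|Lⱼ| then the lexicographically
smallest (left, right) pair, making the choice deterministic and order-free.
Degree-one vertices wire their sole edge against a dummy; vertices whose
edge pairs share no read stay unwired and terminate any walk that reaches
them.

Walks start from degree-one vertices (sorted id order; the output is
invariant to any permutation of this queue, which the tests verify by
permutation). A walk passes through a vertex only when its wiring pairs the
arrival edge with a departure edge; otherwise the blocking vertex (foreign
predecessor, already visited, or unwired) is appended as the terminal step —
consuming the linking edge so no later walk can reuse it — except when the
blocker is already a step of the *current* walk, in which case the walk
stops without appending and the cycle-closing edge stays unused. Components
with no degree-one vertex (pure cycles) are seeded from their smallest-id
wired vertex after the queue drains. The resulting paths are pairwise
edge-disjoint, strictly vertex-simple, and a repeat-contained contig is
interior to at most one path.

Terminal steps appended by the blocking rules are *borrowed*: the blocking
vertex belongs to (or will seed) its own path. Borrowed steps are never
stitched into the borrowing path's scaffold — including them would place the
contig twice and break the one-placement-per-contig conservation guarantee —
and contigs owned by no path (unwired junction vertices) are emitted as
singleton scaffolds instead.

## Stitching and batched assembly

Paths are partitioned by greedy first-fit (descending length) into batches
of ≤ 8192 contigs; a longer path gets its own batch. Within a batch each
path is stitched: for every consecutive pair the linking reads are chained
onto both contigs by unique-k-mer anchors (anchor_k = 21, ≥ 5 anchors on the
densest shared diagonal; uniqueness in both sequences suppresses
repeat-internal anchors), the best read fixes the relative orientation, and
the junction is realized either by inserting the read's intervening bases
(recorded as a read component, so AGP output remains exactly reconstructible)
or by trimming a small overlap from the incoming contig. The first contig of
a path is nominally '+' but the first junction read may flip it — a path
walked antisense to the genome otherwise places its successor on the wrong
side. Junctions with no geometrically consistent read fall back to a run of
100 N.

Two batch-level steps follow, mirroring what a standalone batch assembler
does with a batch's sequences. First, stitched scaffolds are split at the
fallback N-gaps: a junction that none of its own linking reads could place
consistently is either truly unspanned or a chimeric path step, and
repeat-induced edges do produce such steps. Second, a merge pass joins any
two scaffolds of the batch that an unconsumed read bridge connects: the
read is anchor-chained against both full scaffold sequences, the placement
must be linear (no containment, implied overlap ≤ max_junction_overlap =
500 bp — shredded contigs and phase scaffolds never genuinely overlap, so a
large implied overlap marks a repeat-confused chain), and accepted joins are
chained greedily, one partner per scaffold end, cycle-free, in
support-then-anchor-score order. This merge pass, not path length, is what
determines final contiguity: path enumeration is bounded by the reach of
triple-contig read evidence at a single vertex, while read bridges between
path scaffolds are abundant. An external assembler can replace the built-in
route per batch (`backend="external-command"`); it is a thin adapter whose
output is tool-version dependent, and the built-in stitcher is the tested
path.

## Phases and read bookkeeping

- *Expansion*: map ℒ to 𝒞, build, wire, walk, batch-assemble. A read is
  "used" when its link edge ends up internal to an output scaffold or its
  bases were stitched in as gap fill; reads that only link contigs across a
  remaining break stay unused — they are exactly the bridge evidence the
  later phases need.
- *Islands*: unused reads are remapped against the first-generation
  scaffolds. Reads that map are set aside (bridge candidates); the rest fall
  in regions no contig covers and are assembled by the same machinery with
  reads in the contig role (self-hits dropped; the junction overlap cap is
  lifted because read-on-read overlaps are genuine). Island paths of a
  single read are discarded as chaff.
- *Bridges*: the union of both scaffold generations becomes the subject set
  and all still-unused reads the queries; the expansion machinery runs once
  more, and the resulting nested components are flattened back to base
  contigs and reads (orientation, trims and gap runs compose).

The three phases' used-read sets are pairwise disjoint; every input contig
id appears in exactly one final scaffold's component list.

## Synthetic data: what it emulates and what it does not

The generator draws an i.i.d. genome at a given GC (default 0.5), plants
optional repeat families (non-overlapping copies of one unit, mutated to a
target identity), shreds it into contigs (lognormal lengths, mean 5 kb,
CV 0.3; gaps sized so contigs cover 85%; random strands) and samples reads
(uniform starts, normal lengths 10 kb ± 3.4 kb truncated at 1 kb, random
strands, uniform substitutions at 0.2%). These are the packaged study
conditions: a 200 kb genome with one exact 3 kb repeat × 2 at 10× read
coverage, sizes chosen so the full pipeline and its evaluation complete in
seconds while leaving ~35 contigs and ~35 junctions to resolve. Contigs are
shredded directly from the genome rather than assembled from simulated short
reads; this preserves the fragment-length, gap and strand structure a
scaffolder consumes while avoiding any external assembler.

Deliberately not modeled: homopolymer indel errors (HiFi's residual error
mode), chimeric reads, diploidy/heterozygosity, long interspersed repeat
families, and GC-coverage bias. Passing tests therefore demonstrate the
correctness of the graph/wiring/stitching machinery under realistic geometry
— not robustness to every real-data artifact; in particular indel errors
would shift anchor diagonals and require banded rather than exact diagonal
clustering.

## Evaluation

All metrics are computed against simulation truth, not alignment. Each
scaffold component (contig slice or read-fill slice) maps to a genome
interval by composing its slice coordinates, its orientation and its
source's truth placement. A misjoin is an adjacent component pair whose
composed orientations differ, whose genome order contradicts scaffold order,
or whose genome gap deviates from the scaffold gap by more than `slack`
(default 2000 bp ≈ the mapped end length). Genome fraction is the covered
share of the genome; duplication ratio is placed bases over distinct covered
bases; `ngm50` (NG50 after splitting scaffolds at misjoins) stands in for
alignment-based NGA50, which would require a genome aligner.

## Numerical and degenerate-input choices

- All hashing uses fixed splitmix64 constants; no dependence on Python's
  builtin hash. Outputs are byte-identical across runs and platforms.
- Window minimizer ties take the leftmost position; similarity ties in
  mapping are broken by subject id; wiring ties as above; merge ties by
  support, then anchor score, then scaffold ids. Every stage is
  deterministic given its inputs.
- Sequences shorter than k+w−1 yield empty minimizer sets (unmappable, not
  an error); empty mapping degrades the pipeline to contig pass-through
  with a warning; an empty batch list or read set yields empty output.
- IUPAC codes other than N are replaced by N on input with a warning;
  k-mers containing N never become minimizers or anchors.

## Known limitations

- The wiring intersection criterion needs reads mapped to three subjects at
  a vertex; between long scaffolds (later phases) no read can span the
  middle subject, so path enumeration alone cannot chain them — the
  batch-level merge pass carries that load by design.
- Exact-diagonal anchor chaining assumes substitution-only errors.
- The repeat guard (overlap cap) rejects, rather than resolves, junctions
  whose only evidence is repeat-internal; near-tandem repeats longer than a
  read remain unresolvable and surface as scaffold breaks.
- Single-node execution; batches may be stitched across worker processes
  (`n_workers`), with output independent of worker count, but there is no
  distributed mode.
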