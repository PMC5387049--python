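# Methods

## The model

Splicing removes introns at a donor (5', typically `gu`) and an acceptor
(3', typically `ag`) site. Beyond those cores, the working hypothesis of
this package is that introns carry a *paired* consensus — a donor prefix
and an acceptor suffix, written `donor_acceptor` (e.g. `guaagu_ag`) —
and that these paired consensus sequences constitute a code for the
*kind* of alternative splicing the intron undergoes.

The kind of splicing is summarized by the flanking exons. Each unique
exon of a gene receives one of seven splicing types, decided on the
gene's full transcript set:

| type | meaning | operational rule |
|------|---------|------------------|
| R    | retained / invariant | none of the rules below |
| S    | skipped | internal exon absent from a transcript in which its two neighbours are directly joined |
| A5   | alternative 5' splice site | exon variants share the acceptor-side boundary, differ on the donor side |
| A3   | alternative 3' splice site | mirror of A5 |
| ME   | mutually exclusive | non-overlapping exon pair, never co-occurring, each expressed, sharing a flanking exon |
| APr  | alternative promoter | first exon of a transcript, in a gene with >=2 distinct transcription starts |
| APA  | alternative poly-A | mirror of APr at the 3' end |

Donor/acceptor sides are defined on the transcribed strand, so
minus-strand genes are handled after strand normalization. An exon is
given exactly one type with precedence `APr > APA > ME > S > A5 > A3 > R`
(terminal types are positional facts and are decided first; ME is the
most specific internal pattern; R is the default). The precedence is an
argument of `classify_exons` for anyone who wants a different order.

An intron is labelled by its flanking types in transcription order,
`Xa-Xb`. Since APr can only flank upstream and APA only downstream,
exactly 36 ordered pairs are constructible; `enumerate_intron_classes`
returns them in a fixed upstream-major order. When different transcripts
give one intron different flanking pairs, the lexicographically smallest
label is kept (with a warning).

## Consensus discovery

Donor sequences (first `donor_len` = 10 intron bases) feed a quaternary
prefix tree over `{a,c,g,u}`; acceptor sequences (last 10 bases) feed a
suffix tree indexed from the 3' end inward. Each node stores its count,
its branch probability (count / parent count) and the Shannon entropy
(bits) of its children's count distribution.

A *branch* is the edge into a node backed by at least `min_count`
sequences (default 100). Its conservation is measured by two numbers:
the node's branch probability (how forced the step was) and the entropy
at the parent's branching point (how concentrated the choice was). A
branch is selected when its probability is at or above the 95% empirical
quantile of eligible branch probabilities *and* its parent entropy is at
or below the 5% quantile of eligible parent entropies. Both cuts use the
nearest observed value on the kept side (`numpy` quantile methods
`lower`/`higher`), so ties at the threshold are kept. The deepest
selected node on each root-to-leaf path becomes a motif — which is why
motif families of different lengths coexist (`gu_ag` names the paths on
which nothing deeper is conserved, `guaagu_ag` the paths that stay
conserved to depth six).

Pairing the parent's entropy with the child's probability, rather than
using the node's own child-entropy for both, is deliberate: a motif's
end node is precisely the point where continuation becomes free, so its
own child entropy is near-maximal and would veto every true motif end.

Conserved donor motifs x conserved acceptor motifs (restricted to valid
cores: donors starting `gu`/`gc`/`au`, acceptors ending `ag`/`ac`) form
candidate pairs. Every intron is then assigned *exclusively* to the most
specific pair it matches — longest donor prefix, then longest acceptor
suffix, then lowest rank — so the underscore in `gu_ag` means "anything
that matches no more specific consensus". Pairs falling below
`min_count` assigned introns are dropped and assignment re-iterated to a
fixed point; survivors are ranked by descending count (ties broken
lexicographically).

### Capacity of the percentile filters

The number of motifs the 95%/5% filters can certify is bounded by 5% of
the eligible branches. At genome scale (2x10^5 introns) the tree offers
thousands of eligible branches and dozens of motifs; at the desk scale
used here (~5x10^3 introns, `min_count` 100) only ~40 branches are
eligible, so at most three or four branch ends can be certified and two
of them are always the invariant `g`/`gu` core. The recovery studies in
the test-suite therefore run discovery with `min_count=50`
(proportionally still ~20x more conservative than 100 out of 215,155),
which roughly doubles the eligible branches. The package default remains
100.

## Enrichment: the splicing code

For every motif and every one of the 36 classes a 2x2 table is formed
over the full intron universe; introns matching no motif stay in the
universe and contribute to the margins. The exact hypergeometric upper
tail `P(X >= a)` measures enrichment, the lower tail `P(X <= a)`
depletion (scipy's `hypergeom.sf`/`cdf`, computed from log-space pmf
terms, so genome-scale p-values such as 1e-14 are representable).
Significance uses a raw alpha = 0.001 per cell — deliberately no
multiple-testing correction, to match the published reporting
convention; `benjamini_hochberg` is available but off by default. The
code table lists, per class, all ranks enriched and all ranks depleted
at alpha.

## Mutation interpretation

`IVS<intron><+/-k><REF>><ALT>` notation: +1 is the first intron base
from the donor, negative offsets count from the acceptor (-1 the last
base). The interpreter checks the reference base, mutates the junction,
re-assigns the motif and reports the enriched-class sets of the wild and
mutant motifs and their differences. "No motif" is reported distinctly
from "motif with no significant class" — the LKB1 example turns on that
distinction. When the full intron sequence is available, the donor-side
cryptic scan reports, for each of the first `window` (default 100)
intron positions, the most specific donor motif starting there;
acceptor-side scanning is available behind a flag. Note that with a
bare-core motif such as `gu_ag` in the table every `gu` dinucleotide is
a formal hit; `min_motif_length` filters those if undesired.

## U12 branch points

The last 60 bases of each intron are scanned with a log-odds PWM (bits);
the best window per intron enters an empirical distribution and the top
5% are flagged, ties included. The packaged default PWM is built from
the U12 branch-point consensus `uuccuuaac` at 85% per-position
conservation with pseudocount 1 on a uniform background — a documented
construction, not a fitted matrix; user PWMs are accepted as 4-column
TSV or MEME-minimal files. Per class the observed hit count is compared
with the expected count under proportional allocation (class share x
total hits); expected counts sum to the total by construction.

## Within-gene co-occurrence

Ranks assigned to introns of the same gene are pooled per gene; the
association of two ranks is the Jaccard index over genes (Dice and
conditional-probability variants are available), giving a symmetric
matrix with unit diagonal. Ranks are clustered agglomeratively with
average linkage on 1 - association; with no cluster count given the tree
is cut at half the maximum merge distance.

## The synthetic-data generator

`simulate_genome` emits toy genomes (FASTA + GFF3 + ground-truth TSV)
from per-gene templates that instantiate all seven exon types: R-only
genes (one transcript, four exons), S genes (three transcripts skipping
E2, E3, giving a genuine S-S intron), A5/A3 genes (a boundary-shifted
middle exon), ME genes, APr/APA genes (alternative first/last exons).
Default event mix: R 0.35, S 0.25, A5 0.10, A3 0.10, ME 0.05, APr 0.075,
APA 0.075 — weighted toward the alternative events so that every class
used in the studies collects hundreds of introns from ~1,500 genes
(~5,300 introns); the real human class distribution is far more skewed
toward R-R, and no claim about real class frequencies is made from these
runs. Exon lengths 80–160, intron lengths 60–120, strands drawn at
random, ~100 genes per contig.

Background splice sites are canonical: `gu` + positionally biased
interior (donor +3: a 0.45, g 0.35, c 0.10, u 0.10; +4: a 0.40, g 0.30,
c 0.15, u 0.15; uniform beyond) and a pyrimidine-leaning acceptor tract
(u/c 0.30, a/g 0.20) ending `ag`. The bias emulates the strong purine
preference just after real donors and makes discovery non-trivial; a
`uniform_background` stress mode removes it. The default motif plan
plants `guaugu_ag` on R-R introns and `guccug_ag` on R-S introns with
per-gene probability 0.85 — two motifs because that is what the
percentile filters can certify at this corpus size (see capacity above),
with planted continuations chosen off the background-favoured `a`-path
so background contamination of the planted prefixes is negligible.

Planting decisions are per gene, and writes are keyed by splice-site
position (planted wins over background), so introns sharing a donor or
acceptor stay textually consistent. Ground-truth motifs are re-derived
from the actually written sequence, which keeps the truth file exactly
consistent with the emitted FASTA even where shared sites interact.

What the generator does **not** emulate: expression levels and reads,
splicing kinetics, branch-point/ppt realism beyond the planted U12
window, inter-gene sequence homology, overlapping genes, and the heavy
R-R skew of real genomes. Passing the recovery studies therefore shows
that the pipeline's statistics behave as designed under known truth —
not that the discovered human motif set would be reproduced from a real
genome.

Two known statistical consequences of the gene templates: introns
sharing a donor site have identical donor sequences, so motif
assignments are weakly dependent within alternative-boundary classes
(R-A3, R-ME, R-S ...), which inflates Fisher tail variance slightly on
null data; and the within-gene co-occurrence of ranks is likewise
partially structural. Both are noted where tests measure them.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3/GTF converted on
  read. Transcripts with out-of-bounds, zero-length, overlapping or
  abutting exons are dropped with a warning (abutting exons would imply
  a zero-length intron).
* Splice sequences are lowercase sense-strand RNA; `N` in a splice
  window excludes the intron from discovery (a quaternary tree has no
  `N` branch). Introns shorter than the two windows get truncated,
  non-overlapping windows (donor first).
* Intron uniqueness is (contig, strand, start, end) within a gene;
  identical intervals shared by two genes are kept per gene, because
  class labels come from that gene's flanking exons.
* Quantile cuts are observed values (ties kept); rank ties broken
  lexicographically; PWM window ties resolved to the 5'-most window;
  branch-point score ties at the threshold are all flagged.
* Empty motif tables are legal discovery outcomes (thresholds can reject
  everything); `assign_motif` raises on an empty table rather than
  guessing.

## Known limitations

* The seven-type taxonomy forces one label per exon; an exon whose both
  boundaries vary is A5 under the default precedence.
* The selection capacity analysis above means desk-scale runs cannot
  produce tables with dozens of motifs; the published 42-motif table is
  shipped as a fixture for the worked examples instead of being
  re-derived.
* The mutation interpreter reports motif/class shifts; it makes no
  pathogenicity calls and does not model exonic or deep-intronic
  variants.
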