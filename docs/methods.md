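# Methods

## DNA model and coordinates

Molecules are annotated double-stranded DNA, linear or circular, stored as
the top strand (5′→3′) with 0-based half-open intervals. Circular
coordinates are modular; a feature may span the origin (its end exceeds the
length by at most one turn). A linear molecule's top strand runs from the
left top-strand cut to the right top-strand cut, which makes top-strand
lengths additive under digestion and ligation and keeps the length-
conservation invariant exact. Each terminus is a `StickyEnd` (blunt, 5′ or
3′ overhang, with the overhang written 5′→3′ on the protruding strand) that
also remembers the producing enzyme, because reconstructing a ligated
junction needs the flanking recognition context, not just the overhang.

Circular identity is canonical rotation: the lexicographically minimal
rotation of the top strand (Booth's algorithm), also compared against the
reverse complement's minimal rotation. All plasmid equality checks in the
package and its tests use this rotation- and strand-invariant form.

## Enzymes and digestion

The eleven enzymes of the standard (XbaI, SpeI, NheI, AvrII, NdeI, EcoRI,
BamHI, BglII, SphI, PstI, KpnI) ship as a text table of recognition
sequence plus top/bottom cut offsets; the overhang is derived, never
asserted. All eleven recognitions are unambiguous palindromic hexamers, so
a single top-strand scan is complete; ambiguity codes and non-palindromic
(e.g. type IIS) enzymes are rejected at registry load and would require a
two-strand scan. Complete digestion is assumed throughout, matching the
procedures being modelled; partial digests are out of scope.

Digestion of a circular molecule with k cut positions yields exactly k
linear fragments (k+1 for linear input). Cut pairs whose intervals overlap
or touch raise a distinct `SiteCollisionError`, because the fragment
between them would retain no double-stranded core for a ligase to seal; a
circular molecule with no site raises `UncutPlasmid`, a signal distinct
from a hard error. Fragments inherit provenance (source id, cut
coordinates) and sliced, re-anchored copies of part/scar annotations;
recognition-site annotations are dropped and recomputed on demand, since
the cut destroys them.

## Junction (scar) arithmetic

Two ends are compatible iff both are blunt or they share the overhang kind
and their overhangs are reverse complements (identity, for the
self-complementary CTAG/GATC/AATT/TA/CATG/TGCA family shipped here). The
sealed junction's sequence is reconstructed from cut geometry as
`upstream.recognition[:cut_top] + downstream.recognition[cut_top:]` — the
annealed overhang counted once. This reproduces the standard's scar
algebra: same-enzyme joints regenerate the site (AvrII×AvrII → `CCTAGG`,
SpeI×SpeI → `ACTAGT`), isocaudomer cross-joints are dead (AvrII×NheI →
`CCTAGC`, SpeI×XbaI → `ACTAGA`, and likewise for BamHI/BglII). Sites
present in a scar are always recomputed by scanning, never asserted.

Circular ligation enumerates every chemistry-level product of one or two
linear fragments (both relative orientations, deduplicated under canonical
rotation) and annotates each junction as a scar feature. Orientation
selection is deliberately *not* done here: wrong-orientation and
self-ligation products are real chemistry, and the assembly layer's
grammar filter discards them (logged) by demanding forward-strand cassette
features, the expected dead scar, and the expected site census. Ligations
of three or more fragments (concatemers) are out of scope.

## The slot grammar

The eight roles and their flanking contract are fixed data (`SLOTS`), with
the whole transcriptional unit a ninth, composite cassette between XbaI
and SpeI. Part validation enforces role-appropriate cleanliness: TU parts
must not contain the six cassette sites (errors) and are warned about
backbone sites; backbone parts must avoid all eleven. ORF cores must start
with ATG, end with a stop, and contain no in-frame stop; the upstream flank
contributes only `CAT`, so the start codon completes the NdeI site in
frame. RBS parts declare their native Shine–Dalgarno→ATG spacing; the
validator re-measures it (longest, then rightmost SD-like motif; the ATG
sits 3 nt past the core inside the NdeI flank) and warns on disagreement —
spacing is compared exactly, no tolerance, since the platform preserves
native spacing by construction.

Plasmid audits count all eleven sites: duplicated XbaI/SpeI or backbone
sites are errors (they would break further extension or part exchange);
duplicated NheI/AvrII are errors only on single-TU plasmids; NdeI/EcoRI
duplicates — expected one pair per gene — are informational. On fully
unique single-TU plasmids the cyclic site order is also checked against the
standard layout. The number of TUs is inferred from dead XbaI/SpeI joint
scars.

Two regions the standard leaves unspecified are fixed, neutral 6-nt
sequences annotated as linkers: the EcoRI→AvrII spacer (`TGGCAA`) and the
SpeI→BamHI / KpnI→XbaI backbone joints (`CACGTG`), chosen free of all
eleven sites in context. The promoterless degenerate form keeps its empty
slots' flanking sites (an empty ORF slot renders the full `CATATG`
literal), so probe vectors stay extensible.

## Assembly procedures and planning

The four moves (ORF insertion via NdeI/EcoRI, operon extension via
NheI+AvrII into AvrII, cluster extension via XbaI+SpeI into SpeI, slot
swap via the slot's pair) all follow the same pattern: verify site
uniqueness preconditions, digest, select the donor fragment *by feature
annotation* (lengths can tie; features cannot), enumerate ligation
products, and apply the grammar filter, which must select exactly one.
Operon extension on an acceptor with more than one AvrII (a multi-TU
plasmid) is refused with an explicit error rather than guessing a target
site — the procedure being modelled never does this, so the ambiguity is
surfaced, not solved.

A design (ordered TUs, each an ordered run of RBS+ORF genes, plus backbone
choices) compiles to a staged plan: stage 1 inserts every ORF in parallel
into its single-TU vector; each later stage is one cassette transfer —
operon extensions within each TU first (always onto single-TU acceptors),
then TU transfers. A "cloning step" is one stage, so parallel clonings
count once and the stage count always equals the gene count. If any
promoter in the design is inducible (its metadata names a regulator, e.g.
tac→LacI), every stage-1 vector carries the regulator cassette: the final
backbone descends from the first TU's vector, which must end up with the
repressor regardless of which TU uses the inducible promoter.

`execute_plan` runs each step through the simulator and audits the final
product. As an independent cross-check, `assemble_monolithic` writes the
finished construct's sequence down directly — literal flanks, literal
`CCTAGC`/`ACTAGA` scars, no digestion or ligation code — and the tests
require canonical-rotation identity between the two routes for both the
dual-gene operon and the two-TU cluster, as well as for the whole
seventeen-construct reference series' spot checks.

## Gene design

Reverse translation is deterministic and greedy: each residue gets its
most frequent codon, plus the preferred stop. Forbidden-site removal is
strictly synonymous: violations are scanned left to right; for each, the
candidate replacement codons overlapping the site are tried in descending
usage (ties broken by position, then codon text) and the first
substitution that destroys that occurrence wins, iterating until clean
with a convergence guard. The scan includes the cloning-context boundaries
(`CAT` upstream, `GAATTC` downstream) so no site can straddle the flanks
once the part is installed. The default forbidden set is the six cassette
enzymes; the fixture generator passes all eleven so synthetic reporters
are also backbone-safe. The bundled codon-usage table is synthetic,
illustrative fixture data in the style of a moderately GC-rich
*C. glutamicum* profile — frequencies sum to 1 per residue, but no claim
is made that they reproduce any published table; users supply a real table
for production work. Unbreakable sites raise a named error; with hexamer
sites spanning at most three codons and every violation containing at
least one degenerate codon in practice, the error path is contract, not
expectation.

## Synthetic fixtures: what they do and do not show

The generator emits stand-ins for every part class — three promoters and
three RBSs carrying the platform's measured strength ranks, two reporter
ORFs designed by the gene designer (brightness constants 34 and 16
1/(mM·cm)), a terminator, three host replicons with their copy-number
metadata, an *E. coli* replicon, marker and regulator — at realistic
lengths (promoter ~200 nt, RBS ~20 nt, ORF 300–720 nt, terminator ~150 nt,
backbone parts ~0.7–1.1 kb). Sequences are random but scrubbed so the
flanked context contains no stray standard site; RBS cores embed an
`AGGAGG` motif with a G-free tail matching the declared spacing. A single
seeded generator drives all randomness; identical seeds give byte-identical
registries, and the bundled default registry is the fixed seed 2012.

Passing tests on these fixtures demonstrates the *structural* claims —
slot grammar, scar algebra, site censuses, plan sizes, round trips — on
sequences with the standard's exact topology. They do not demonstrate
anything about real regulatory sequences: no promoter motifs, RBS
thermodynamics, codon-usage fidelity or expression levels are modelled,
and the strength ranks are carried metadata, not predictions. Construct
ranking is therefore a strict partial order over qualitative ranks
(incomparable configurations stay incomparable); no numeric expression is
ever produced. The published pTGR5 record (NCBI JX559328) can be imported
by users who want real sequences; nothing in the package requires it.

## Problem sizes and determinism

The test suite and the acceptance script use small, fixed problem sizes
chosen to exercise every code path: randomized digestion/ligation suites
run ≥200 cases each on 30–400 nt molecules, gene-design invariance runs
200 random proteins of 4–51 residues, extension closures go to three genes
/ three TUs, and the full reference series is 17 constructs of ~3.5–5.6 kb.
Every random draw flows through explicitly seeded generators (hypothesis
suites are derandomized), so the whole suite is reproducible run to run.

## Known limitations

Methylation sensitivity, star activity, nicking and type IIS enzymes,
partial digests, ligation efficiency and concatemer products are not
modelled. Only one- and two-fragment ligations are enumerated. Targeted
extension inside an existing multi-TU cluster (duplicated NheI/AvrII) is
refused rather than solved. SBOL serialisation and primer design are out
of scope; GenBank, FASTA, JSON and YAML are the interchange formats, with
sticky ends carried in a documented GenBank comment dialect because the
flat-file standard has no overhang field.
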