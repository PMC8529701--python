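# Methods

This note documents the models, conventions and design choices behind
phytofoundry, in the spirit of a methods appendix: what is simulated, what
is assumed, and where the package's behaviour is a deliberate choice among
several defensible ones.

## Type IIS cut geometry

Both toolkit enzymes are modeled by three numbers: a non-palindromic
recognition sequence, a spacer length, and an overhang length. Defaults
are the standard vendor geometries — BsaI-class `GGTCTC`, spacer 1,
overhang 4; BpiI/BbsI-class `GAAGAC`, spacer 2, overhang 4 — and both are
configurable through `EnzymeSpec`. For a sense-strand site whose
recognition occupies `[i, i+6)`, the top-strand cut falls at
`t = i + 6 + spacer` and the 4-nt 5' overhang is `seq[t:t+4]`; antisense
sites cut symmetrically upstream (`t = q − spacer − 4`). Coordinates are
0-based, half-open, always on the top strand. Circular molecules are
scanned through a doubled window so origin-spanning sites are found, and
cut positions are reduced modulo the length.

Degenerate inputs: a molecule with no site raises an explicit
"undigestible" error rather than returning itself; cuts closer together
than one overhang length raise a geometry error; on linear molecules,
sites whose cut or overhang would run off an end are dropped, and terminal
fragments carry empty-string overhangs (blunt ends never ligate).

## Ligation and assembly

Ligation is exact top-strand identity of 4-mer overhangs. Mismatch and
partial ligation are out of scope, as is ligation fidelity modeling.
Self-complementary (palindromic) overhangs would permit inverted ligation
that this model cannot represent; they are excluded with a warning (none
occur in the toolkit grammar). `ligate_cyclic` enumerates *every* distinct
circular product over fragment subsets — including self-circularization
and competing products when two inserts share overhangs — with products
compared up to rotation via the lexicographically minimal rotation
(Booth's algorithm). This mirrors what a one-pot reaction can actually
produce and is cross-checked in the tests against a brute-force
permutation search.

`assemble` is the stricter designer-facing operation: it requires a unique
circular product using the acceptor backbone and every insert exactly
once. Failure modes are distinguished deliberately — a missing junction
names the overhang pair nobody supplies, competing products raise an
ambiguity error, and an insert whose body retains a recognition site
raises a domestication error. A successful product is verified to contain
no recognition site of the assembly enzyme on either strand; this is the
defining convergence property of Golden Gate, and it also means a product
cannot be re-digested with the same enzyme — round-trip checks therefore
recover insert bodies from the recorded junction coordinates (provenance
spans) rather than by re-cutting.

Part sequences in the registry are full circular plasmids: level-0
storage plasmids for tag/CDS parts (insert flanked by inward-facing
BsaI-class sites) and expression plasmids for acceptors (dropout cassette
carrying outward-cutting sites). `assemble` digests all of them and
excises the unique site-free fragment of each, so the same machinery
serves part validation, assembly and level-0 creation.

## Reading-frame conventions

The phytobrick junctions fix translation frames; the package adopts one
consistent layout:

* `AATG` junction — the start codon is bases 2–4 of the overhang.
  Tagless acceptors carry an in-frame stop immediately upstream, so the
  open reading frame begins exactly at the junction.
* Expression-tag acceptors encode MEKKI in the backbone with its own ATG
  upstream of the junction; the final Ile codon closes on the junction's
  first base. The ORF extractor anchors at the `AATG`-embedded ATG and
  extends upstream in frame to the 5'-most ATG before an in-frame stop,
  which resolves both layouts without special-casing.
* `CCAT` junction — the N-tag's start codon is the overhang's `AT` plus
  the first body base (forced to `G`); the tag's final codon closes on the
  first `A` of the downstream `AATG` junction. The junction ATG then reads
  as an internal methionine of the fusion.
* `TTCG` junction — generated CDS bodies keep `len(body) ≡ 0 (mod 3)`, so
  the junction reads `TTC-G` (the "frame2" register) and frame2 C-tags
  begin with a G-initial codon. The frame1 HiBiT C-tag variant
  (`NNT-TCG` register) is generated for registry completeness but is, by
  construction, out of frame with frame2 CDSs; designs pair registers
  deliberately.

Premature stops are reported with their nucleotide position when a stop
codon precedes the C-tag span; translation uses the standard genetic code
throughout. Protein masses use the standard average residue-mass table
with one water (18.0153 Da) per chain (monoisotopic variant available);
tag detection is exact substring match of the named motifs (MEKKI, the
S-tag 15-mer, the canonical 11-residue HiBiT peptide, the strep motif).
Protease motifs cut TEV at `ENLYFQ↓(G|S)`, thrombin at `LVPR↓GS`,
Factor Xa at `I(E|D)GR↓` and HRV 3C at `LEVLFQ↓GP`, returning the index of
the residue after the scissile bond.

## Reaction layout parameters

`ReactionLayoutConfig` defaults (units in the field names): 2000 nl
reaction = 1735 nl master mix + 265 nl sample; 26.6 ng template per
reaction (13.3 ng/µl final); 65 000 nl source fill; 2.5 nl droplet
quantum; 30 000 nl dead volume. The droplet quantum is the acoustic
instrument's transfer granularity; requested volumes are rounded half-up
to the nearest quantum, which reproduces both boundary cases of interest
(a 100.4 ng/µl stock maps to exactly 265 nl of plasmid and no water; a
200 ng/µl stock to 132.5 nl + 132.5 nl water). The dead volume is
calibrated so the default budget yields 20 transfers per master-mix well,
matching observed practice; instrument dead volumes vary, so it is an
explicit config field rather than a constant. Destination wells fill
column-major from A1 with replicates adjacent; plate geometry is fixed at
384 wells for source and destination. Stocks too dilute to deliver the
target mass within the sample volume raise a concentration error naming
the construct — silently under-dosing a reaction would corrupt a screen.

## Quantification

The standard curve is a linear model with intercept, fitted by ordinary
least squares; the intercept absorbs the blank. Linearity across the
0.01–2 nM calibrated range is an assumption of the detection chemistry,
not something the package verifies — the `out_of_range` flag is the guard,
and the simulation tests show why it matters: readings near the bottom of
the range inherit the intercept's fit error, so samples should be diluted
into mid-range. Sample statistics use the n−1 denominator; a single
replicate reports an undefined (NaN) standard deviation rather than zero.
Kinetic reads select the timestamp nearest 18 min by default. Fluorescent
(GFP) quantification is relative only, as a ratio to a named reference
well.

## Assay calculators

Glucosylation adds `C6H10O5` (glucose minus water); the substrate must
offer a hydroxyl (≥1 O, ≥1 H). Adduct m/z uses monoisotopic element
masses (C 12, H 1.0078250319, N 14.0030740052, O 15.9949146221) plus
charge-carrier shifts (+1.007276 H, +22.989218 Na, +18.033823 NH4), all
singly charged, rounded half-up to one decimal — the resolution at which
MRM transitions are entered on a triple quadrupole. Monoisotopic masses
reproduce all six toolkit transition-list values at that precision. The
probe-annealing check is exact reverse-complement matching at the probe's
3' end; no hybridization thermodynamics.

## What the synthetic generator emulates — and what it does not

`fixtures` exists because the real toolkit plasmid sequences are not
bundled. It generates, deterministically from a seed, full plasmids that
are *grammar-correct*: right categories and fusion sites, printed tag
peptides reverse-translated into the right registers, bodies free of both
enzymes' recognition sites on both strands, CDS bodies stop-free in
frame, and the in-frame stops that anchor ORF extraction. Reverse
translation samples codons uniformly over synonyms with bounded
rejection-resampling to avoid forbidden sites.

What it does not emulate: real backbone content (origins, promoters,
markers are random domesticated DNA), codon-usage realism, the actual
sequences of large tags (GST, MBP, TrxA, SUMO and fluorescent proteins
are short synthetic placeholder peptides), or any expression biology.
Passing tests therefore demonstrate the *logic* of the workflow — grammar,
assembly, frames, bookkeeping — on sequences with the right structure;
they say nothing about expression yields, folding or activity, which are
experimental outcomes outside this package's scope.

The plate-reader simulator draws multiplicative lognormal noise (unit
mean, CV as configured, default 2%) around the linear response, with
standards as a two-fold serial dilution across the calibrated range in
triplicate.

## Problem sizes and determinism

Default simulation sizes keep the whole suite small: 2.5-kb backbones,
300–900 nt screen CDS bodies, an 11 × 8 = 88-construct screen, 384-well
picklists, 100-replicate curve-recovery runs. The full test suite runs in
a few seconds on one CPU. All randomness flows from explicit seeds
(Python `random.Random` for sequences, NumPy `default_rng` for plate
noise); the same seed reproduces every sequence byte for byte.

## Known limitations

* Single-level ("terminal acceptor") assembly only; no hierarchical
  multi-gene assembly systems.
* Exact-match ligation; no overhang-fidelity or mismatch modeling.
* No codon optimization or expression-yield prediction — deliberately, as
  part reuse is favoured over per-system optimization.
* The frame1/frame2 C-tag registers are modeled but not auto-matched to a
  CDS; choosing compatible registers is the designer's responsibility, as
  it is at the bench.
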