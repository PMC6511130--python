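# Methods

## Panel model

An amplicon is (forward primer, reverse primer, insert length). The
insert length counts the biological bases **between** the two primers
(primers excluded); the simulator and evaluator use the same convention,
so the system is self-consistent even though panel vendors vary on this
point. Sequences are uppercased on parse; the only degenerate base
supported is N: an N in a primer matches any read base, while an N in a
read (an uncalled base) matches nothing but a primer N. Full IUPAC
degeneracy is out of scope.

## Primer search

**k-mer index.** Every primer contributes its 1-base-shift k-mers
(default k = 8) under four roles: forward and reverse primers as seen at
5′ ends, and both reverse complements as seen at 3′ ends of read-through
reads. k-mers containing N are not indexed (wildcard expansion is
exponential); N handling is deferred to verification. Hit lists are
sorted (primer, role, offset) so all downstream tie-breaks are
deterministic and reproducible.

**k-mers model.** Seeds are taken at read offsets 0…`buffer_len`
(default 12, i.e. 13 attempts), so a primer is findable even behind a
few junk bases. A seed hit at primer offset *o* implies placement
`read_start = s − o`; negative placements and placements truncated by
the read end are discarded. Verification is whole-primer Hamming
distance — not just the seed — so the reported cost is the primer's true
mismatch count and "best match" is well defined. Ties in cost break
toward the lower primer index (panel order). A cost-0 hit stops the
search early; this affects speed only, since 0 is globally minimal.
When a placement implies junk bases before the primer, the trim removes
`[0, read_end)`: those bases are not insert sequence.

**Dynamic model.** Invoked only when seeding fails, which is how indels
present (an indel between seed and primer start breaks the placement
arithmetic, and a verified placement straddling an indel has a large
Hamming cost). All k-mers of the search prefix (max primer length +
buffer) are tallied per (primer, role); the single top candidate (ties
to the lower primer index) is aligned by semi-global Needleman–Wunsch:
match 0, mismatch −1, gap −1 (gap open = gap extend; no separate opening
penalty), primer aligned end-to-end, anchored at text position 0, with a
free text suffix. The score therefore equals minus the edit distance to
the best-matching read prefix, and the alignment's text end is the trim
boundary. Score ties resolve to the smallest text end. Only the top
candidate is aligned; scoring the full ranked list would triple the
alignment cost for no measurable gain on separated panels.

**Quality filter.** `--minqual` thresholds the mean Phred score of the
full read, computed before trimming; 0 disables. Mean (rather than
minimum or windowed) keeps the statistic insensitive to isolated bad
cycles. Encoding detection: any code <59 ⇒ Phred+33; all ≥64 with at
least one ≥75 (impossible under +33) ⇒ Phred+64; otherwise Phred+33.
The preprocessing scan is bounded to the first 10,000 records per file —
the search window is sized by primer lengths, so an exact global maximum
read length is unnecessary.

## Trim geometry

After 5′ removal, the read-through condition is triggered exactly when
the remaining length exceeds the matched amplicon's insert length. The
partner primer's reverse complement is then scored by Hamming distance
at offsets within ±5 (`readthrough_slack`) of the expected boundary
(offset = insert length), absorbing small indels while staying
deterministic. The primer may be truncated by the read end; at least k
overlapping bases are required, since shorter overlaps are statistically
unverifiable and are left in place. Ties resolve to the offset closest
to the expected boundary, then the smaller offset. Untrimmed reads are
written to the main output by default (`--drop-untrimmed` to exclude);
quality-dropped pairs are counted but not written, and a drop always
removes both mates.

## Simulator

The generator emulates the benchmark conditions: `n_amplicons` (default
50) primer pairs of 18–25 bp, inserts of 90–180 bp on 150 bp reads
(mixing read-through and normal geometries), `depth` (default 100) read
pairs per amplicon, exactly `errors_in_primer` substitutions planted
uniformly in every primer copy (each substitution changes the base; with
probability `indel_prob` one becomes a 1-bp indel), insert bases kept
error-free so the metrics isolate primer matching, all qualities Q30,
and `negative_fraction` (default 10%) of the total dataset as
primer-free uniform-random pairs. Panels are rejection-sampled so any
two primers (either orientation, prefix-aligned) differ by more than
2×5 bases, making ground truth unambiguous at every tested allowance.
Insert lengths producing a 3′ partner overlap of 1…k−1 bases are
redrawn: such overlaps are unverifiable by design, so they would make
exact trimming impossible for a whole amplicon regardless of the
matcher. Everything derives from one integer seed; outputs are
byte-identical across runs.

What the simulator does **not** model: platform error profiles
(quality-dependent miscalls, homopolymer indels), errors in insert
bases, chimeric amplicons, or reference-genome-derived panels. Passing
benchmarks therefore demonstrate the matcher's behaviour under
controlled primer-region errors, not end-to-end performance on real
instrument data.

## Evaluation

Per read, joined on read id: TPR = primer-bearing reads with ≥1 base
removed / all primer-bearing reads; TNR = primer-free reads with 0 bases
removed / all primer-free reads; ACC = primer-bearing reads whose output
is byte-equal to the true insert (already truncated at the read end for
normal-condition reads) / all primer-bearing reads. ACC ≤ TPR by
construction. Empty classes yield NaN, never 0.

## Expected behaviour under planted errors

With exactly *e* substitutions planted in every primer copy, a read is
findable by the k-mers model only if at least one seed window (k
consecutive primer bases within the 12-bp buffer) is error-free, and by
the dynamic model only if at least one window anywhere in the primer is
error-free. For 18–25 bp primers at k = 8, enumeration over all error
placements gives a ~4–6% chance at e = 2 that no usable window survives,
rising steeply to >60% at e = 5: sensitivity on this generator is
bounded near 96–98.5% at e = 2 and degrades sharply beyond e = 3, with
specificity pinned at 100% by panel separation. This is an intrinsic
property of exhaustive per-copy error planting — real primer synthesis
error rates (~1/300–600 per base) leave most primer copies with 0–1
errors, where sensitivity is effectively 100%.

## Problem sizes

Default test and benchmark sizes — 50 amplicons, 100 pairs per amplicon,
~11,000 reads per condition — give metric standard errors around 0.15
percentage points while a full simulate→trim→evaluate cycle completes in
seconds.

## Known limitations

- The dynamic model needs at least one exact k-mer hit to nominate a
  candidate; heavily damaged primers (no clean window) are unmatched.
- 3′ partner overlaps shorter than k bases are deliberately left
  untrimmed.
- Solexa+64 (pre-1.3) quality scores and interleaved FASTQ are
  unsupported; BAM-based soft-clip trimming and non-primer 3′ adapter
  removal are out of scope.
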