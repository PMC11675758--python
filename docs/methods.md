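# Methods

## The codec

The scheme transcodes a binary message `B` of length `n` into a DNA strand
in five steps:

1. **Binarization (optional).** If the input is itself DNA, it is first
   binarized at 2 bits per base with the payload translation table
   (T→00, G→01, C→10, A→11). Raw bytes are unpacked MSB-first, 8 bits per
   byte; 0/1 text is used as-is.
2. **Word split.** `B` is cut into 3-bit words `w = b2 b1 b0`, right-padded
   with zeros to a multiple of three (`pad ∈ {0,1,2}`).
3. **Zero extension.** Each word becomes `w′ = 0‖w`, a 4-bit word with the
   same numeric value, matching the 4-bit vectors of the spatial domain.
4. **Codebook lookup.** `w′` maps to a `(base, cluster)` pair. The
   two-dimensional spatial domain places the four base vectors once in each
   of two half-planes (Cluster 0 and Cluster 1): in Cluster 0 the base
   vectors carry the 2-bit suffixes 00/01, in Cluster 1 the suffixes 10/11.
   In closed form: `base = Table(b2 b0)` under the payload translation
   table, `cluster = b1`. The bases form the payload.
5. **Primer.** The cluster-bit stream is taken two bits at a time
   (right-padded with one 0 if odd) through a second translation table
   (A↔00, T↔01, G↔10, C↔11) and prepended as the primer, a metadata channel
   half the payload's length. The synthesized strand is `primer‖payload`.

Decoding inverts each step: split off the leading `T − ⌊2T/3⌋` bases of a
`T`-base strand as the primer (exactly `T/3` when the payload length is
even), expand it to cluster bits, look each `(base, cluster)` pair up in
the inverted codebook, drop the zero MSBs, concatenate, and truncate to the
original bit length.

## Length model and metrics

For an `n`-bit message, `payload = ⌈n/3⌉`, `primer = ⌈payload/2⌉`,
`total = payload + primer`. Three metrics summarize a run:

* **bpn** — `bits stored / total bases`. Exactly 2.0 iff `n ≡ 0 (mod 6)`;
  otherwise slightly below, approaching 2.0 as `n → ∞`. The ceiling
  operators dominate tiny messages (bpn = 0.5 at `n = 1`; the value
  exceeds 1.5 from `n = 8` on). bpn is printed at 9 significant figures.
* **Compression ratio** — `CR(%) = S_out/S_in × 100` over symbol counts
  (input bits vs output bases); exactly 50% whenever `n` is divisible
  by 6.
* **GC content** — `(|G| + |C|)/n` of the output strand, a proxy for
  thermal stability of synthesized oligos. Both the raw GC count and the
  fraction are reported.

Benchmark text files are conventionally accounted at 8 bits per sequence
character (ASCII), not 2 bits per base; `capacity_table` and the
`capacity` CLI command support both accountings (`--bits-per-char`).

## Design choices

* **Codebook completion.** Five of the eight codebook entries are pinned
  by the traced worked example; the remaining three (0100→(C,0),
  0110→(C,1), 0111→(A,1)) follow from the closed-form rule above, which is
  the unique completion consistent with the cluster-suffix construction of
  the spatial domain. The codebook is a data-driven bijection object, so an
  alternative layout over the same domain can be injected; bijectivity is
  validated at construction.
* **Padding side.** Message bits are right-padded with zeros to a multiple
  of three, and an odd cluster stream is right-padded with one zero. The
  right side is chosen so that the worked example and the ceil-based
  length model are reproduced unchanged.
* **Pad disambiguation.** Nothing in the strand itself distinguishes
  message bits from pad bits, so `EncodedMessage` carries
  `original_bit_length`, persisted in the FASTA description line as
  `ascdna_bits=<n>` (or in a `<file>.meta.json` sidecar with `--sidecar`,
  for pipelines that strip descriptions). When absent, it defaults to
  `3 × payload` — no pad assumed.
* **Two translation tables.** The payload and primer channels use
  different base↔bit tables (payload: 00↔T, 01↔G, 10↔C, 11↔A; primer:
  00↔A, 01↔T, 10↔G, 11↔C); both are implemented as printed in the scheme's
  definition, without attempting to unify them.
* **Alphabet policy.** Lowercase input is canonicalized; any non-ACGT
  character (including IUPAC ambiguity codes such as N) is a hard error
  naming the offending position. An opt-in `--skip-invalid` policy drops
  such characters and records the count in the record metadata.
* **Bit containers.** Bit strings are plain Python `str` of `'0'`/`'1'`:
  at the message sizes this codec targets (≤ a few megabits) this is fast
  enough and keeps every intermediate trivially inspectable.
* **The primer is metadata, not biochemistry.** No melting-temperature,
  homopolymer or specificity constraint is imposed on it.

## Fixtures and what the tests show

The fixtures module carries the fully traced 60-bit golden example
(every intermediate view: words, extended words, bases, clusters, primer),
seeded uniform random bit/base generators, and the bit counts of the
standard 11-sequence DNA benchmark corpus (two chloroplast genomes, five
human genes, two mitochondrial and two viral genomes) — sizes only, so no
download is needed; capacity tabulation depends only on bit counts.

Random fixtures are i.i.d. uniform. Real archival data is neither uniform
nor patternless, but the codec's output lengths — hence bpn and CR — depend
only on the input's bit count, never its content, so uniform fixtures fully
exercise the length behaviour. What uniform fixtures do *not* show is the
GC balance of the output for structured inputs: under uniform bits the
output GC fraction converges to 0.50 (tested at 100,000 bits with a
binomial tolerance), but biased real inputs can produce GC-skewed or
homopolymer-rich strands, and the scheme contains no constraint coding to
prevent that.

Round-trip identity is tested exhaustively for all messages up to 12 bits
and on 1,000 seeded random messages up to 300 bits; the length law is
checked for all `n ≤ 10,000`; the capacity model is checked against the
benchmark corpus values to 5×10⁻⁹ absolute (one corpus row's published
figure is inconsistent with the model that reproduces the other ten and is
excluded as a typo). The acceptance script evaluates the closed-form model
at full corpus sizes after cross-checking it against actual encodings of
6,000-bit messages matched to each corpus size's residue mod 6 — the only
feature of `n` the ceiling terms depend on.

## Limitations

* No error-correcting code: a single base substitution corrupts 2–3
  message bits, and an indel desynchronizes the remainder of the strand.
* No biochemical constraint handling (GC window, homopolymer runs,
  synthesis-length fragmentation into oligos).
* The decoder requires the primer/payload boundary implied by the length
  law; truncated or concatenation-damaged strands are rejected rather than
  repaired.
* Random access within a strand and hash-based addressing are out of
  scope.
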