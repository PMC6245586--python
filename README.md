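# mitescan

Structure-based detection of **miniature inverted-repeat transposable
elements (MITEs)** in eukaryotic genome sequences.

MITEs are short (50–800 bp) non-autonomous class II transposons present at
high copy number in plant and animal genomes. They carry no coding
sequence, so they cannot be found by homology to transposase genes; what
identifies them is pure structure: a pair of **terminal inverted repeats**
(TIRs, ≥ 10 bp, at most one interior mismatch) spanning the element, and a
**target site duplication** (TSD, 2–10 bp, identical on both sides)
created on insertion. `mitescan` searches a genome for exactly this
architecture and then separates real, mobile elements from structural
look-alikes.

## Method

1. **Seed search.** Each chromosome is scanned in 10 kb fragments
   overlapping by 800 bp (the maximum element length, so nothing is split).
   Every overlapping 10-mer is hash-indexed; a *seed* is a pair of 10-mers
   where one equals the reverse complement of the other, exactly or with a
   single interior substitution, spanning 50–800 bp. Low-complexity words
   (≥ 8 bp homopolymer or dinucleotide runs, or < 20 % G+C or A+T) are
   rejected.
2. **Merging.** Seeds on one anti-diagonal whose left starts step by +1
   (right starts by −1) describe one growing TIR and are merged; a single
   interior mismatch produces a characteristic 2-base gap between a perfect
   and an imperfect seed, which is bridged. A merge that would combine two
   distinct mismatch positions is refused.
3. **TSD validation.** The longest identical 2–10 bp word immediately
   flanking both element ends is the TSD (a 2 bp TSD must be `TA`);
   candidates without one are rejected. Because a self-complementary TSD
   junction (e.g. `TA`) is itself absorbed into the inverted repeat, the
   caller also probes symmetrically trimmed boundaries.
4. **Likelihood scoring.** Every 6-mer *s* gets
   `F(s) = log2( Pr(s|M) / Pr(s|N) )` from a positive set *M* of trusted
   MITEs and a null set *N* of structural false positives
   (add-pseudocount smoothed). A candidate's score is the mean of F over
   its overlapping 6-mers — length-free — and only candidates scoring
   strictly above 0 survive.
5. **Flank filter.** Candidates extended by 60 bp flanks are aligned
   all-by-all (Smith–Waterman, +1/−1 match/mismatch, −2/−1 gaps). A real
   MITE has a partner elsewhere matching at > 80 % identity *within* the
   element but not into the flanks; segmental duplications (flanks match
   too) and partnerless singletons are removed.
6. **Families.** Surviving elements (without flanks) are aligned under a
   strict criterion (≥ 90 % identity over ≥ 90 % of both elements); matches
   are edges of a similarity network, connected components with ≥ 3 members
   are families, and the member of highest degree is the family
   representative. TSDs assign superfamilies: `TA` → Stowaway, `TAA` →
   Tourist, 5/6/8 bp → hAT, 9/10 bp → Mutator.

## Worked example

The package ships a simulator that implants MITEs with a known truth
table, so the whole pipeline can be exercised without downloads:

```bash
mitescan simulate -o sim --length 60000 --n-families 3 --copies-per-family 4 --seed 11
# synthetic genome with 12 implants -> sim
mitescan train sim/positive.fasta sim/null.fasta -o model.tsv
# model written to model.tsv
mitescan find sim/genome.fasta -o out --model model.tsv
# 12 MITE sequences in 3 families -> out
```

`out/report.tsv` (1-based inclusive coordinates) begins:

```
record_id    start  end    tir_length  tsd     mismatch_position  score     family_id  superfamily  is_representative
synthetic_1  4527   4776   12          GATCCA                     1.717233  1          hAT          1
synthetic_1  7509   7758   12          TA                         1.633920  2          Stowaway     1
synthetic_1  9590   9839   12          GATCCA                     1.706082  1          hAT          0
```

Each row is one retained element: a 250 bp element whose 12 bp TIRs face
each other, flanked by the TSD shown; the score is the mean 6-mer
log-likelihood ratio (positive = more MITE-like than background); the
three implanted families come back as three families with one
representative each, classified by their TSDs. `out/mites.fasta` holds all
retained elements, `out/representatives.fasta` one exemplar per family,
and `out/superfamily_counts.tsv` per-chromosome superfamily counts.

For a real genome, train the model on curated MITE sequences (e.g.
Repbase-derived) versus structural false positives from your genome, then
run `mitescan find genome.fasta --model model.tsv`.

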