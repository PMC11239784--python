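# gh13tools

A toolkit for delineating subfamilies within the main α-amylase family
GH13 of the CAZy classification — the *in silico* workflow by which groups
such as the *Thermotoga*-like maltogenic amylases (GH13_48) and the
*Haloarcula*-like α-amylases (GH13_49) are separated from each other and
from their closest established relatives (e.g. GH13_38).

It is aimed at protein-family bioinformaticians who need the complete
chain of evidence for a new subfamily as reusable, tested code:

1. **Redundancy clustering** (`gh13tools.cluster`) — greedy centroid
   clustering at a 50 % identity threshold (UCLUST-style first-match
   semantics, BLOSUM62 global alignments, identity over the shorter
   ungapped length).
2. **CSR anchoring and fingerprints** (`gh13tools.csr`) — GH13's seven
   conserved sequence regions (CSR-I…CSR-VII) laid out on a 52-position
   logo coordinate system (CSR-VI 1–9, CSR-I 10–15, CSR-V 16–20, CSR-II
   21–29, CSR-III 30–37, CSR-IV 38–43, CSR-VII 44–52) with the catalytic
   triad anchored at D25 / E34 / D43. The scheme is projected onto an
   alignment through a reference sequence, and the extracted block yields
   conservation counts, position frequency tables, sequence-logo tables
   (IC\_p = log₂ 20 − H\_p, height = f·IC), and motif fingerprints such as
   GH13_48's L-[DN] (positions 19–20) or GH13_49's [WY]-[GA] (28–29).
3. **Profile classification** (`gh13tools.classify`) — per-subfamily
   position-specific log-odds profiles,
   score(p, a) = log₂((n₍p,a₎ + βq₍a₎)/(N₍p₎ + β)/q₍a₎),
   with a margin rule (default 5 bits) that leaves ambiguous queries
   unassigned.
4. **Distance phylogeny** (`gh13tools.phylogeny`) — the alignment trimmed
   to the catalytic TIM-barrel span (start of CSR-VI to end of CSR-VII),
   pairwise-deletion p/Poisson distances, neighbor joining, and
   column-resampling bootstrap supports.
5. **Structure superposition** (`gh13tools.superpose`) — Kabsch
   least-squares Cα superposition over the canonical A+B+C domains with
   iterative pruning (default cutoff 2.0 Å), reporting the matched-Cα
   count and RMSD.
6. **Synthetic benchmark** (`gh13tools.synth`) — seeded generators for
   subfamily-labelled sequence sets whose CSR positions are conserved at
   configurable probabilities, and toy Cα structures with known rigid
   transforms.

## Worked example

```python
from gh13tools import csr, synth
from gh13tools.pipeline import clade_supports, conservation_report, loo_accuracy
from gh13tools.phylogeny import bootstrap_support, trim_to_barrel

cfg = synth.load_benchmark_config()            # shipped 4-class benchmark
bench = synth.make_benchmark(list(cfg["specs"].values()),
                             cfg["n_per_class"], seed=1)
aln = bench.alignment                          # 345 sequences, 210 columns
cmap = csr.anchor_csr_columns(aln, aln.records[0].id, bench.refmap)
matrix = csr.extract_csr_block(aln, cmap)

ids48 = [s for s, l in bench.truth.items() if l == "GH13_48"]
stat = csr.conservation_count(matrix, {19: {"L"}, 20: {"D", "N"}}, ids48)
print(f"L-[DN] conserved in {stat.count} of {stat.total}")
print(f"LOO accuracy: {loo_accuracy(matrix, bench.truth):.3f}")

tree = bootstrap_support(trim_to_barrel(aln, cmap), n_replicates=100, seed=1)
print(clade_supports(tree, bench.truth))
```

prints

```
L-[DN] conserved in 261 of 300
LOO accuracy: 1.000
{'GH13_38': 100, 'GH13_48': 100, 'GH13_49': 100, 'intermediary': 100}
```

i.e. the L-[DN] motif is observed at 87 % of the maltogenic-amylase-like
class (its generating level is 86.2 %), every sequence is returned to its
own subfamily by leave-one-out profile classification, and all four
classes are monophyletic with 100 % bootstrap support in the
neighbor-joining tree of the trimmed barrel region.

A command-line interface mirrors the library
(`gh13 simulate | cluster | csr | classify | tree | superpose | run`);
`gh13 run --config pipeline.yaml` executes the full delineation and writes
TSV/Newick outputs plus a deterministic JSON report.

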