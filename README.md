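# vectorint

Characterization of plasmid-vector integration events in small haploid
genomes from short-read resequencing and assembly contigs.

Given a reference genome, a linearized transforming vector (which may carry
segments copied from the host genome) and paired-end reads from a transformed
line, the pipeline:

1. maps reads jointly against genome + vector with a built-in fixture-scale
   seed-and-extend mapper (soft-clips, pair flags, unique/ambiguous status) —
   external SAM from a real aligner is accepted too;
2. computes mapping statistics (coverage, mapped %, insert sizes);
3. profiles per-base depth, masks vector intervals shared with the host
   genome, reports vector integrity (covered fraction, per-feature
   intact / partially deleted / deleted verdicts) and estimates transgene
   copy number as the marker / housekeeping coverage ratio;
4. extracts junction evidence (discordant genome–vector read pairs,
   soft-clipped split reads, clipped-end hints) and clusters it into
   insertion locus calls with per-side support, breakpoints and
   both_ends / left_only / right_only status;
5. classifies structural variation at the locus: target-site duplications,
   target deletions, blunt joins, filler insertions (with origin: vector
   duplicate / genome derived / unknown), vector truncations, internal
   inversions, inverted duplications, tandem multi-copy inserts, and
   adjacent large deletions — from junction geometry, a windowed depth scan,
   and maximal-exact-match anchor chaining of assembly contigs (a
   machine-readable dot plot).

A synthetic transformant generator (`vectorint.simulate`) produces
ground-truthed fixtures — reference, vector with host-derived segments,
insertion events from a preset taxonomy (`T3`, `T6`, `T12`, `T14`, `T16`,
untransformed `NT`), 2×101 bp paired reads and locus contigs — so the whole
pipeline runs and is tested with no external data.

## CLI

```bash
# write a ground-truthed fixture directory (FASTA/FASTQ/GFF3/BED/JSON + config)
vectorint simulate --preset T3 --seed 1 --out fixtures/T3

# run the full analysis; writes report.json, loci.bed, svs.tsv, ...
vectorint characterize --config fixtures/T3/config.yaml --out runs/T3

# score the report against the fixture truth (exit 1 on mismatch)
vectorint verify --report runs/T3/report.json --truth fixtures/T3/truth.json

# human-readable summary
vectorint report --report runs/T3/report.json
```

The characterize config is a single YAML (paths relative to the config file,
module parameters under `params:`); `simulate` emits a ready-made one.

## Python API

```python
from vectorint.simulate import simulate_line
from vectorint.pipeline import characterize, verify_against_truth

sim = simulate_line("T3", seed=1, depth=100)
report = characterize(
    reference=sim.reference.as_dict(),
    vector_seq=sim.vector.sequence,
    vector_features=list(sim.vector.features),
    pairs=sim.reads,
    contigs=[sim.contig],
    line="T3",
)
card = verify_against_truth(report, sim.truth.to_json_dict())
assert card["ok"]
```

## Layout

```
src/vectorint/
  simulate.py    ground-truthed transformant generator (presets, reads, contigs)
  alignment.py   seed index, toy mapper, mapping stats, SAM/GFF3 I/O
  coverage.py    depth profiles, copy number, homology masking, integrity
  junctions.py   junction evidence extraction and locus clustering
  svcalls.py     breakpoint reconciliation, filler origin, anchor chaining
  pipeline.py    orchestration, per-line reports, truth scoring
  cli.py         simulate / characterize / verify / report
```
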