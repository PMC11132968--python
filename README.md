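# gemmatlas

Tools for quantifying **transcription-factor promoter reporter activity in
Marchantia polymorpha gemmae**, and for designing the standardized promoter
parts such reporter collections are built from.

The gemma — the clonal propagule of Marchantia — is a lenticular disc with
two opposing apical notches that house the stem-cell populations. Because its
morphology is so stereotyped, fluorescence reporter activity can be reduced
to a one-dimensional profile along the axis through the two notches and
compared across hundreds of reporter lines. `gemmatlas` implements that
comparison end to end, plus the sequence-design workflow for the reporters
themselves:

1. **Image stage** — maximum-intensity projection, rolling-ball background
   subtraction, rotation aligning the two notch landmarks with the x-axis,
   and a rectangular plot-profile (per-column mean) of the reporter channel.
2. **Normalization stage** — cubic smoothing spline (`spar = 0.4`, the R
   `smooth.spline` convention λ = r·256^(3·spar−1)), piecewise-linear
   landmark alignment of (start, notch1, notch2, end) onto common reference
   positions, left/right folding about the axis midpoint
   (out(x) = ½·[in(x) + in(1−x)]), and max normalization.
3. **Domain stage** — hierarchical clustering (Euclidean distance, complete
   linkage) of the folded profiles, silhouette-based selection of the cluster
   count, the intensity-weighted mode of each cluster mean, and rule-based
   anatomical labels (SCZ/DDCZ, TZ, PZ, CZ-biased ubiquitous, even
   ubiquitous).
4. **Catalog stage** — five non-exclusive expression categories per reporter
   (no signal, dim, ubiquitous, notch, specialized) with count/percentage
   summaries, concordance of categories with asinh-transformed RNA-seq
   abundance (asinh x = log(x + √(x²+1))), and centered PCA of cell types
   over their reporter flags.
5. **Part design** — extraction of a 1.8 kb promoter window upstream of the
   TSS plus the entire 5′UTR from FASTA + GFF3; 5′UTRs < 500 bp fuse into a
   single `PROM5` part, 500–3,000 bp give separate `PROM` and `5UTR` parts,
   longer 5′UTRs and promoters with N-runs near the TSS are excluded;
   Type IIS domestication removes every BsaI (GGTCTC) and SapI (GCTCTTC)
   site by deterministic single-base substitutions; parts are emitted with
   Golden Gate fusion sites (`PROM5` GGAG→AATG, `PROM` GGAG→TACT, `5UTR`
   TACT→AATG) and assembly is checked by overhang bookkeeping.

A synthetic-data module generates gemma images, profile matrices, toy
genomes and expression tables with known ground truth, so the entire
pipeline is testable offline.

## Worked example

```python
import gemmatlas as g
from gemmatlas.normalize import normalize_matrix
from sklearn.metrics import adjusted_rand_score

matrix, truth = g.make_profile_set(n_per_archetype=40, noise_sd=0.1, seed=1)
folded = normalize_matrix(matrix)                       # smooth, align, fold, max-normalize
k = g.select_k(folded.to_numpy(), (2, 8))               # -> 5
clustering = g.assign_domains(g.cluster_profiles(folded, g.ClusterConfig(k=k)))
print(k, adjusted_rand_score(truth, clustering.labels))
for cid, mode in sorted(clustering.mode_positions.items()):
    print(cid, round(mode, 3), clustering.domain_labels[cid])
```

prints

```
5 1.0
0 0.2 SCZ/DDCZ
1 0.2 TZ
2 0.2 PZ
3 0.499 CZ-biased ubiquitous
4 0.184 even ubiquitous
```

i.e. the five planted expression domains are recovered exactly (adjusted
Rand index 1.0): three notch-peaked clusters of increasing spread whose
mode sits at the notch landmark (0.2 on the folded axis), one cluster
peaking at the gemma center (0.5), and one near-constant cluster whose mode
position is not meaningful. The scripts in `examples/` walk through each
capability the same way (image rendering and profiling, clustering, catalog
summaries, part design).

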