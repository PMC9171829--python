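# speccons

Consensus spectrum generation and quality evaluation for clustered tandem
mass spectra.

When MS/MS spectra are clustered — for building spectral libraries or for
speeding up database searches — each cluster of near-identical spectra must
be reduced to a single *representative* (consensus) spectrum. How that
reduction is done affects everything downstream: identification rates,
score distributions, and whether post-translational modification sites are
mapped consistently. `speccons` implements the four standard reduction
strategies side by side, plus the statistics needed to judge how faithfully
a representative reflects its cluster, and a seeded simulator so all of it
can be tested without real instrument data. It is aimed at proteomics and
metabolomics informaticians who post-process the output of clustering tools
such as spectra-cluster or MaRaCluster.

## The four methods

For a cluster *C* = {s₁, …, sₙ} of centroided spectra:

- **AVERAGE** — pool all member peaks, then greedily merge peaks whose m/z
  lies within a tolerance (default 0.02 Th) of the running group mean;
  each group becomes one peak with m/z = Σᵢ mᵢIᵢ / ΣᵢIᵢ (intensity-weighted)
  and intensity = the arithmetic mean of the group.
- **BIN** — assign every peak to a fixed half-open bin [k·w, (k+1)·w) with
  w = 0.02 Th; discard bins to which fewer than 25 % of the *distinct*
  members contribute (strictly fewer — exactly 25 % survives); emit one
  peak per surviving bin with unweighted mean m/z and intensity.
- **MOST** — the medoid: vectorize each member on the same 0.02 Th grid,
  normalize to unit Euclidean norm, and select argmaxᵢ Σ_{j≠i} ⟨vᵢ, vⱼ⟩.
- **BEST** — the member whose peptide-spectrum match (PSM) score is best;
  undefined (and skipped, with a count) for clusters in which no member
  was identified.

Representative quality is evaluated on *multispectral* clusters (≥ 2
members with one peptidoform covering > 50 % of the member PSMs): a
representative identified as the majority peptidoform is *high-quality*;
one matching a minority member or no member at all is *low-quality*.
Between-method agreement is reported as *corroborative* (same peptidoform),
*divergent site* (same sequence, different modification sites) and
*divergent peptide* PSMs.

## Worked example

```sh
python examples/01_consensus_methods.py
```

```
cluster cluster_0001: 5 members, template has 40 peaks
  cluster_0001:member_1: 41 peaks, similarity to template 0.601
  cluster_0001:member_2: 43 peaks, similarity to template 0.899
  cluster_0001:member_3: 43 peaks, similarity to template 0.514
  cluster_0001:member_4: 42 peaks, similarity to template 0.741
  cluster_0001:member_5: 40 peaks, similarity to template 0.907

AVERAGE: 65 peaks (similarity to template 0.957)
BIN:     49 peaks (similarity to template 0.911)
MOST selected cluster_0001:member_5 (the medoid member)
BEST selected cluster_0001:member_5 (score 92.9)
```

Five noisy replicates of a 40-peak template are combined: the
peak-combining methods (AVERAGE, BIN) reconstruct the template better than
any single member (similarity 0.957 / 0.911 vs. a best member of 0.907),
while the member-selecting methods (MOST, BEST) both choose member 5, the
replicate closest to the template. `examples/02_cluster_quality.py` and
`examples/03_file_workflow.py` walk through the evaluation statistics and
the file-based (MGF/TSV) workflow.

The same operations are available from a shell:

```sh
speccons simulate --out-dir data --n-clusters 50 --members 4 --seed 1
speccons consensus --mgf data/spectra.mgf --clusters data/clusters.tsv \
    --method bin --out consensus.mgf --report report.json
speccons evaluate --clusters data/clusters.tsv --member-psms data/psms.tsv \
    --rep-psms reps.tsv --out quality.tsv --summary summary.json
```

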