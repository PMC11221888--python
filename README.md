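# niee — network information entropy of edges

Complex diseases often progress through a sudden, irreversible shift —
a *tipping point* — preceded by a short pre-disease window in which a
small module of genes shows sharply increased expression fluctuations and
mutual correlations (the dynamic-network-biomarker signature). `niee`
detects that window from a **single perturbed sample** compared against a
reference cohort, without training a model: it measures how much the
appended sample disturbs an information-entropy statistic defined on
every edge of a protein–protein interaction background network.

It is written for computational biologists analysing time-course or
staged bulk expression data who want per-sample early-warning scores, a
screened "key local network" of recurrently disturbed edges, and
plot-ready trajectory/landscape tables.

## The score

For an edge *E = (g₁, g₂)* of the background network (confidence-filtered,
with isolated nodes and degree-one edges pruned), each endpoint *gₓ* with
*M* first-order neighbours gets a normalised correlation entropy over *s*
samples,

    H_gx(s) = −(1/log M) Σ_y  p_xy(s) log p_xy(s),
    p_xy(s) = |PCC_xy(s)| / Σ_y |PCC_xy(s)|,

where *PCC* is the Pearson correlation between the gene and neighbour
*y*. With node degrees α, β as weights, the edge entropy and edge
standard deviation are

    H_E(s)  = α/(α+β) · H_g1(s)  + β/(α+β) · H_g2(s)
    SD_E(s) = α/(α+β) · SD_g1(s) + β/(α+β) · SD_g2(s).

Appending one perturbed sample to the *s* reference samples and
recomputing gives *H_E(s+1)*, *SD_E(s+1)*, and the per-edge differential
score

    ΔH_E(s+1) = |SD_E(s+1) − SD_E(s)| · |H_E(s+1) − H_E(s)|.

Averaging ΔH_E over all edges yields the global score ΔGH of the sample;
averaging over a screened key edge set yields the key-local score ΔLH.
Edges that repeatedly reach the top fraction of ΔH_E across perturbed
samples form the key local network, and a sharp jump of the score
trajectory above its running history is flagged as an early-warning
signal.

## Worked example

A synthetic 50-gene study with a 5-gene module whose variance triples
and whose internal correlation surges at the sixth of ten time points:

```python
from niee import (SyntheticScenario, make_network, make_reference_cohort,
                  make_perturbed_series, score_sample, trajectory, detect_signals,
                  top_fraction_edges, select_key_network)

scenario = SyntheticScenario(seed=2)           # 50 genes, tipping at t06
net = make_network(scenario)
reference = make_reference_cohort(scenario, net)
series, truth = make_perturbed_series(scenario, net)

results = [score_sample(net, reference, vec, label=label) for label, vec in series]
traj = detect_signals(trajectory(results))
for label, score, flag in zip(traj.labels, traj.values, traj.flags):
    print(f"{label}  dGH = {score:.6f}  {'<-- early-warning signal' if flag else ''}")

tops = [top_fraction_edges(r, fraction=0.05) for r in results]
key = select_key_network(tops, min_frequency=2, top_fraction=0.05)
print(f"\nkey local network: {len(key)} edges")
module = {tuple(e) for e in truth["module_edges"]}
print(f"planted module edges recovered: {len(set(key.edges) & module)}/{len(module)}")
```

Output:

```
t01  dGH = 0.000733
t02  dGH = 0.000891
t03  dGH = 0.001512
t04  dGH = 0.000410
t05  dGH = 0.000354
t06  dGH = 0.002380  <-- early-warning signal
t07  dGH = 0.000368
t08  dGH = 0.001564
t09  dGH = 0.000949
t10  dGH = 0.000897

key local network: 19 edges
planted module edges recovered: 5/10
```

The global score jumps at the planted tipping point t06 and is flagged
there; the screened 19-edge key network recovers half of the module's
internal edges (an equal-size random edge set would recover ~12% on
average).

The same pipeline is scriptable from the shell:

```bash
niee simulate --seed 7 --outdir run/fixtures
niee score  --network run/fixtures/network.tsv --score-scale unit \
            --expression run/expression.tsv --metadata run/fixtures/samples.tsv \
            --outdir run/scores
niee keynet --score-dir run/scores --top-fraction 0.05 --min-frequency 2 \
            --outdir run/key
```

For scikit-learn users, `NieeScorer` (fit on the reference cohort,
`transform`/`score_samples` on perturbed samples) and
`KeyNetworkSelector` compose with `sklearn.pipeline.Pipeline`.

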