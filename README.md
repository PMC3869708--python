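# pridenet

Social network analysis of fission–fusion animal groups, built around the
kind of observational dataset a field team collects on a small closed
social unit — here, a 12-member lion pride monitored up to three times a
day: group-composition scans (who was within the grouping threshold when
the group settled) and directed social-interaction bouts (play, head-rubbing
greeting, social licking), plus a roster and a kinship matrix.

The package takes those delimited-text logs to:

* **Association matrices** under the gambit of the group, using a modified
  simple ratio index `X / (X + Y_A + Y_B)` — for a dyad {A, B}, `X` counts
  scans with both present and `Y_A`/`Y_B` scans with exactly one present;
  the classical `Y_AB` term (seen simultaneously in different groups) is
  excluded as unobservable from a single platform.
* **Directed interaction matrices** per behaviour and combined, after
  bout de-duplication (repeat records of the same directed behaviour less
  than one minute apart are one bout).
* **Network metrics**: density, strong transitivity over directed triples
  (`min`/`max`/`any` closure rules), weighted in/out-degree with explicit
  normalization, betweenness centrality `B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st`
  (Brandes' algorithm; σ_st = number of shortest s→t paths), and maximal
  cliques (Bron–Kerbosch with pivoting).
* **Inference**: Mantel matrix-permutation tests of each network against
  the others and against attribute matrices (kinship, sex, age,
  half/full-sibling indicators) and density-matched random nulls; Spearman
  and Kendall tau-b correlations among node metrics, with leave-one-out
  sensitivity checks; a keystone-candidate ranking across networks.
* **A synthetic pride simulator** with planted structure (grouping
  preference ρ, kin-biased Poisson interaction rates `λ_ij ∝ (1+r_ij)^β`,
  a boosted keystone individual, cub-driven play) so every stage of the
  pipeline is testable end to end without field data.

The full analysis is run twice — on the whole roster and with a subset
(typically the cubs) excluded — mirroring the dual reporting convention of
developmental/field studies.

## Worked example

```python
from pridenet import ngamo_like_config, simulate_pride, run_analysis, RunConfig

obs, truth = simulate_pride(ngamo_like_config(n_days=450, seed=1))
print(len(obs.scans), len(obs.events))   # 1816 9564

bundle = run_analysis(RunConfig(n_permutations=1000, seed=1), observations=obs)
rep = bundle.variants["all"].reports["composition"]
print(rep.density)                        # 1.0
print(rep.node_metrics["betweenness"].max())   # 0.0

panel = bundle.variants["all"].mantel
row = panel[(panel.matrix_a_name == "kinship") & (panel.matrix_b_name == "all_social")]
print(float(row.r.iloc[0]), float(row.p_value.iloc[0]))   # 0.763 0.000999
```

The simulated campaign produces ~1.8k composition scans and ~9.6k
interaction bouts. The composition network has density 1 — every dyad was
seen together at least once, so the group is spatially cohesive — and
consequently betweenness 0 for every individual (on a complete graph no one
lies *between* anyone). The kinship × all-social Mantel correlation is
strongly positive (r ≈ 0.76) at the smallest attainable p-value for 1000
permutations (1/1001 ≈ 0.001): individuals interact preferentially with
kin, exactly the structure the simulator planted.

The same pipeline is scriptable from the shell:

```bash
pridenet simulate --seed 1 --days 450 --out sim/
pridenet analyze --scans sim/scans.csv --events sim/events.csv \
    --roster sim/roster.csv --kinship sim/kinship.csv --out run/
pridenet mantel run/all/attribute_kinship.csv run/all/matrix_all_social.csv
pridenet metrics run/all/matrix_play.csv --directed
```

`analyze` writes, per roster variant: labelled matrix CSVs, GraphML
sociograms, group-metric and per-node tables, the Mantel panel (tidy and
block layouts), the correlation suite, clique membership lists, a keystone
ranking, and a JSON manifest recording every option, seed and record count.

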