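# edphylo

Phylogenetic comparative analysis of **embryonic developmental period (EDP)**
— the days from the start of incubation to hatching — in auks (Alcidae) and
penguins (Spheniscidae).

Across birds, EDP scales with fresh egg mass; for Charadriiform birds the
relationship is the power law

    predicted EDP (days) = 17.18 · (egg mass in g)^0.119

Auk and penguin EDPs are mostly *longer* than this prediction, and the
interesting biology lies in the residual variation: does it track proxies of
nutrition (clutch size, foraging habitat, activity pattern) and predation
risk (nest type)?  Because species are not independent data points, the
regression of EDP residuals on those predictors must account for shared
ancestry.  This package provides the full pipeline:

1. **Allometric residuals** — `EDPr = EDP − 17.18·m^0.119` per species
   (`edphylo.allometry`).
2. **Trees** — rooted phylogenies with Newick/Nexus I/O, outgroup rooting,
   pruning, the Brownian-motion variance–covariance matrix
   `V[i,j] = root-to-MRCA(i,j) distance`, and strict majority-rule consensus
   of MCMC tree samples with burn-in discard (`edphylo.trees`).
3. **PGLS with Pagel's λ** — the generalized least squares model
   `y = Xβ + ε`, `ε ~ N(0, σ²·V(λ))`, where `V(λ)` multiplies the
   off-diagonal covariances by λ (λ = 1: pure Brownian motion; λ = 0: star
   phylogeny).  λ is estimated by profile maximum likelihood; coefficients,
   standard errors, t statistics (both df conventions, both tails) and a
   whitened-space r² are evaluated at λ̂ (`edphylo.pgls`).
4. **Synthetic data** — seeded Yule tree, Brownian-trait and full
   regression-dataset simulators with known truth, for parameter-recovery
   and type-I calibration studies (`edphylo.synthetic`).
5. **Pipeline + CLI** — the packaged 33-species trait table, reconciliation
   of table and tree, the end-to-end analysis report, and `edphylo`
   subcommands `residuals`, `consensus`, `pgls`, `reproduce-paper`,
   `simulate` (`edphylo.pipeline`, `edphylo.cli`).

## Worked example

The study's own consensus tree was never published with branch lengths, so
the package ships a clearly-labelled **synthetic stand-in** tree (accepted
genus-level topology, node-depth branch lengths).  Running the analysis on
the packaged table with it:

```python
import edphylo as e

table = e.load_paper_table()       # 33 auk + penguin species
tree = e.load_standin_tree()       # synthetic stand-in topology
report = e.run_paper_analysis(table, tree)
print(report.to_text())
```

prints (abridged):

```
n_taxa = 31
lambda_hat = 0.982687
r_squared = 0.239226
df = 31 (n_taxa); markers use one-sided p

   variable  coefficient       se         t  p_one_sided  p_two_sided marker
  intercept    21.364757 5.790294  3.689753     0.000429     0.000858     **
clutch_size    -5.762108 2.602047 -2.214452     0.017141     0.034282      *
   foraging     0.997614 1.593835  0.625921     0.267974     0.535949
   activity    -3.368176 2.117582 -1.590577     0.060926     0.121853
       nest    -3.072846 2.297924 -1.337227     0.095439     0.190879
```

Read it as: two penguins are dropped for missing foraging data (n = 31);
λ̂ ≈ 0.98 says the residuals are strongly phylogenetically structured
(near-Brownian), so ordinary least squares would be anticonservative;
species with two-egg clutches develop markedly faster (≈ 5.8 days shorter
EDP), diurnal and open-nesting species somewhat faster, and offshore
foragers slower but not significantly so.  Coefficient *magnitudes* and r²
depend on the tree's branch lengths — with a tree re-inferred from the
cytochrome-*b* accessions listed in the packaged table (an external step;
this package never downloads data) the clutch-size coefficient is expected
near −8.3 and r² near 0.44.

The same analysis from the shell:

```sh
edphylo reproduce-paper --tree my_consensus.nwk --out-dir results/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged trait table through the allometry pipeline,
the EDP residuals of five benchmark species (razorbill, emperor penguin,
little blue penguin, Cassin's auklet, spectacled guillemot) and writes them
as JSON, then runs one simulated-data PGLS fit end-to-end as a self-check.

See `docs/methods.md` for the model, its assumptions, numerical choices and
known limitations.
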