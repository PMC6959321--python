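# guildnet

Signed co-occurrence network analysis for microbiome OTU tables: build a
Spearman correlation network, detect dense clusters ("ecological guilds")
with a from-scratch MCODE implementation, and dissect a guild's internal
cooperation/competition structure — sub-guilds, guard and civilian nodes, and
phylum-pair positive-to-negative (P/N) link ratios.

## The problem

Species abundance profiles across samples encode interaction structure: OTUs
(operational taxonomic units — 16S sequence clusters acting as species
proxies) whose abundances rise and fall together are candidates for
cooperation, while anti-correlated OTUs suggest competition. In the healthy
human oral microbiome, this kind of analysis reveals a striking motif: the
strongest network cluster is an alliance of *Firmicutes* and *Bacteroidetes*
standing against *Actinobacteria*, organised into two internally cooperative
sub-guilds connected only by negative links carried by a minority of "guard"
taxa. `guildnet` packages the full analysis pipeline behind that kind of
finding, plus a planted-structure simulator to validate it.

## Method

1. **Filter** — drop OTUs with total reads < 30 across all samples
   (singleton removal).
2. **Network** — for every OTU pair compute Spearman's rank correlation *R*
   (mid-ranks for ties) with a two-sided p-value from the t approximation
   *t = R√((n−2)/(1−R²))*; keep an edge iff |*R*| ≥ 0.6 and *p* ≤ 0.05
   (inclusive). Edges carry sign(*R*). The P/N ratio = positive/negative edge
   counts summarises the cooperation–competition balance.
3. **Clusters** — MCODE: weight each vertex by the density of the highest
   k-core of its closed neighbourhood (or by the clustering coefficient
   *C_i = 2n/(k_i(k_i−1))* in `simple_clustering` mode), expand clusters
   from locally heaviest seeds down to a weight cutoff `(1−vwp)·w(seed)`,
   then post-process (2-core test, haircut, optional fluff). Score =
   density × size.
4. **Guild analysis** — partition a cluster into sub-guilds by positive-edge
   connectivity; classify each node as *guard* (negative edges only towards
   other sub-guilds), *civilian* (no negative edges) or *anomalous*
   (negative edge inside its own sub-guild); tabulate phylum composition and
   per-phylum-pair P/N ratios.
5. **Simulation** — Gaussian-copula counts with negative-binomial margins
   over a factor-model latent correlation that plants two antagonistic
   blocks with designated guards, plus background and rare OTUs; Spearman
   structure follows the copula identity ρ_S = (6/π)·asin(ρ/2).

## Worked example

Classify the packaged reference guild (55 oral OTUs, 39 negative
inter-sub-guild correlations):

```bash
$ python examples/01_fba_guild_roles.py
ASG: 14 guards, 7 civilians
FBSG: 16 guards, 18 civilians
guild composition: {'Actinobacteria': '21 (38.2%)', 'Firmicutes': '14 (25.5%)',
                    'Bacteroidetes': '9 (16.4%)', 'Others': '11 (20.0%)'}
```

Every endpoint of a cross-sub-guild negative edge is a guard; the 14-vs-16
split and the phylum mix expose the *Firmicutes*+*Bacteroidetes* alliance
facing *Actinobacteria*. End-to-end recovery on simulated data
(`examples/04_planted_recovery.py`, 200 samples):

```
top cluster: 42 nodes, score 33.46
sub-guilds found: [28, 14], balanced=True
  partition_ari: 1.000
  guard_precision: 1.000
  guard_recall: 1.000
```

i.e. the pipeline re-identifies every planted guard from edge signs alone and
the sub-guild partition matches the planted blocks exactly.

The same pipeline is scriptable from the shell:

```bash
guildnet simulate --out-dir sim/            # synthetic table + ground truth
guildnet all sim/otu_table.tsv --out-dir out/   # filter -> network -> MCODE -> guild report
```

## Layout

- `src/guildnet/otu_io.py` — table/label/phylum I/O and packaged fixtures
- `src/guildnet/netbuild.py` — filtering, Spearman network, topology stats
- `src/guildnet/mcode.py` — MCODE clustering
- `src/guildnet/guilds.py` — sub-guilds, roles, phylum summaries
- `src/guildnet/synthetic.py` — planted-structure count simulator
- `src/guildnet/cli.py` — `guildnet` command-line pipeline
- `docs/methods.md` — model, parameters, numerical choices, limitations
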