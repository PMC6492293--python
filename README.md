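# discoursenet

Discourse network analysis for coded media statements: map who agrees with
whom across a policy debate and detect the discourse coalitions that emerge.

The pipeline:

1. **statement_store** — read/validate statement tables (CSV or JSON: one row
   per coded statement with article, source, date, person, organization,
   actor type, concept, and an agree/disagree flag), slice them into
   half-open time windows, stratify by publication.
2. **stance** — aggregate statements into a per-actor, per-concept stance
   matrix with a net-stance reduction (+1 support / −1 reject / contested /
   absent).
3. **network_builder** — project the stance matrix into weighted actor–actor
   networks. Tie weight = concepts jointly supported + jointly rejected −
   concepts with opposing stances (the *subtract* transformation), divided by
   the pair's average statement count (*average-activity normalization*), and
   thresholded at ≥ 0.4 (configurable). Congruence-only and conflict-only
   networks are also available; subtract = congruence − conflict.
4. **community** — Girvan–Newman edge-betweenness clustering on the
   unweighted thresholded graph with a modularity-maximizing dendrogram cut;
   per-actor tie counts and *external ratios* (share of ties leaving the
   actor's coalition).
5. **concept_stats** — per-window concept frequency tables with a
   contestedness score (min/max of agree vs disagree counts) and optional bar
   plots.
6. **synthetic_data** — a seeded corpus generator with planted polarized
   coalitions, brokers, heavy-tailed actor activity, and per-window alignment
   drift, so the whole pipeline is testable without access to a coded corpus.

## CLI

```sh
discoursenet simulate --seed 7 --out out/sim
discoursenet validate --input out/sim/corpus.csv
discoursenet build-network --input out/sim/corpus.csv --threshold 0.4 --out out/net
discoursenet cluster --input out/sim/corpus.csv --out out/cluster
discoursenet external-ratio --input out/sim/corpus.csv --out out/ratio
discoursenet concepts --input out/sim/corpus.csv --n-windows 3 --plots --out out/concepts
discoursenet report --input out/sim/corpus.csv --by-source --out out/report
```

Defaults mirror the canonical analysis: organization-level actors, subtract
transformation with average-activity normalization, threshold 0.4, three
equal time windows. All outputs are deterministic given the input and seed
(sorted CSVs, byte-identical across repeated runs). Usage errors exit 2,
data errors exit 1.

## Layout

```
src/discoursenet/    statement_store, stance, network_builder, community,
                     concept_stats, synthetic_data, cli, errors
tests/               pytest suite incl. brute-force oracles (tests/oracles.py)
                     and tests/test_acceptance.py
scripts/acceptance.py
```
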