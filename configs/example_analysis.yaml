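# Example end-to-end analysis: simulate a trial-scale cohort and compare
# three switching strategies under 12-weekly CD4 monitoring.
# Run with:  cloneweight run --config configs/example_analysis.yaml --out out/
cohort:
  synthetic:
    n_individuals: 2946
    n_intervals: 65
    seed: 1
strategies:
  - strategy_id: cd4_100
    cd4_threshold: 100
  - strategy_id: cd4_50
    cd4_threshold: 50
  - strategy_id: who4_only
mode: hg          # threshold linear (h) + event-only dummies (g)
horizon: 60       # 240 weeks
truncation: 10
bootstrap: 0      # set e.g. 500 for percentile confidence bands
seed: 1
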