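# Quick-look analysis of the demo study (run from the directory holding
# the `study/` folder written by `crowdvoc simulate`).
metadata_path: study/screenings.tsv
compound_path: study/compounds.tsv
out_dir: results-demo
permutation_k: 20
model: {n_trees: 200, seed: 7}
seed: 7
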