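# Demo: near-isogenic-line drought study, full replication, default noise.
mode: in_vivo_study
out_dir: scratch/demo_run
seed: 42
genotypes: [lox2, B73, lox4]
treatments: [control, drought]
replicates: 3
plants: 5
spectra_per_day: 12
days: [0, 1, 2, 3, 4, 5, 6, 7]
band: carotenoid_1157
d_start: 0
d_end: 7
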