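# Default synthetic recording campaign: 18 subjects, five acquisitions
# (T0..T4) x two conditions (C1 rest, C2 task), ten 5-s epochs per cell,
# 256 Hz, 19-channel 10-20 montage.
n_subjects: 18
time_points: [T0, T1, T2, T3, T4]
conditions: [C1, C2]
epochs_per_cell: 10
epoch_seconds: 5.0
fs: 256.0
channels: [Fp1, Fp2, F3, F4, C3, C4, P3, P4, O1, O2,
           F7, F8, T3, T4, T5, T6, Fz, Cz, Pz]
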