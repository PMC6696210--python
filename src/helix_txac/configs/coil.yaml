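# Synthetic 8-loop receive array around a disk object: pseudo-replica
# SNR map plus GRAPPA g-factor maps at the listed accelerations.
grid_n: 64
pixel_mm: 4.0
n_loops: 8
array_radius_mm: 140.0
loop_radius_mm: 50.0
object_radius_mm: 90.0
noise_rho: 0.2
noise_sigma: 0.02
n_replicas: 128
accelerations: [2, 3, 4]
seed: 3
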