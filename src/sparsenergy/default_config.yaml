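# Default ATP budget: measured per-spike and resting costs, ten glial cells
# per neuron, and the 3 Hz lower bound of the 3-4 Hz mean rate of retinal
# ganglion cell populations.  All energies in ATP molecules (per spike or
# per second).
budget:
  e_spike_gen: 3.84e8
  e_propagation: 3.28e8
  e_rest_neuron: 3.42e8
  e_rest_glia: 1.02e8
  glia_per_neuron: 10
  firing_rate: 3.0
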