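"""Generate a synthetic amplitude series and inspect its structure.

Builds the default desk-scale scenario — a 64-electrode array, 20 current
amplitudes from 0.1 to 4 uA with one hardware breakpoint, 20 trials each —
and prints the scale of the artifact against the spike templates, which is
the crux of the separation problem.
"""

import numpy as np

import stimsort as ss

ds = ss.simulate_dataset(ss.SimConfig(), seed=1)
data, truth = ds.data, ds.truth

es = data.stim_electrodes[0]
nonstim = [e for e in range(data.E) if e != es]
print(f"array: {data.E} electrodes, {data.T} samples at {data.sampling_rate_hz:.0f} Hz")
print(f"amplitudes: {data.J} from {data.amplitudes[0]:.2f} to {data.amplitudes[-1]:.2f} uA, "
      f"breakpoint at {data.breakpoints[0]:.2f} uA, {data.n_trials[0]} trials each")

a_lo = np.abs(truth.centered_artifact()[1][nonstim]).max()
a_hi = np.abs(truth.centered_artifact()[-1][nonstim]).max()
a_stim = np.abs(truth.centered_artifact()[-1][es]).max()
ei_peaks = [ds.eis.peak_strength(n) for n in ds.eis.neuron_ids]
print(f"peak artifact (non-stim electrodes): {a_lo:.0f} uV at the 2nd amplitude, "
      f"{a_hi:.0f} uV at the top; {a_stim:.0f} uV on the stimulating electrode")
print(f"spike-template peaks: {', '.join(f'{p:.0f}' for p in ei_peaks)} uV "
      f"-> artifact and spikes overlap in amplitude, so naive subtraction fails")
print(f"ground truth: {truth.spikes.n_spikes()} spikes across "
      f"{sum(data.n_trials)} trials")
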