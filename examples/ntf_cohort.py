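"""Decompose a cohort of evoked trains into priming-state pools.

Generates a 12-synapse cohort with the wild-type-like preset (binomial
release noise, sweep averaging), factorizes the synapse x frequency x
stimulus tensor, and compares the recovered tight-state pools (M_TS)
and common fusion probability with the generator's ground truth.
"""

import numpy as np

from synprime import TrainTensor, WT_MINUS, gen_train_cohort, ntf_decompose

table, truth = gen_train_cohort(WT_MINUS, n_synapses=12,
                                freqs=(20.0, 50.0, 100.0, 200.0, 333.0),
                                seed=7, noise="quantal", n_sweeps=10)
tensor = TrainTensor.from_long(table)
result = ntf_decompose(tensor, n_components=3, n_restarts=3, seed=7,
                       ridge=1e-3)

m_ts_true = np.array([truth["synapses"][k]["M_TS"]
                      for k in sorted(truth["synapses"])])
rel_err = np.abs(result.M_TS - m_ts_true) / m_ts_true

print(f"residual (masked rel. Frobenius): {result.residual:.4f}")
print(f"estimated p_fusion: {result.p_fusion:.3f}  "
      f"(generating value {truth['synapses'][next(iter(truth['synapses']))]['p_fusion']})")
print(f"median M_TS recovery error: {100 * np.median(rel_err):.1f}%")
print(f"per-synapse f_TS: {np.round(result.f_ts, 2)}")

print()
print("Loadings are pre-stimulus pool sizes (vesicle counts); the slope of")
print("m_1 against M_TS through the origin estimates the common fusion")
print("probability of tightly docked vesicles.")
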