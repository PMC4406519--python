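"""Compile a Bayesian network from cohort-learned models and query a patient.

A synthetic cohort stands in for a real longitudinal study: priors and
empirical dose-response tables are estimated from it, the best of the seven
patterns is fitted per factor-complication pair, and the CPTs are filled by
the naïve-Bayes combiner at each bin's representative value. The compiled
network then answers patient queries by exact enumeration — including for
patients with missing factors, which are summed over their population
distribution.
"""

import numpy as np

from diabrisk import DiscretizationScheme, FactorObservation, default_config, \
    generate_cohort, infer
from diabrisk.pipeline import learn_network

schemes = {
    "hba1c": DiscretizationScheme("hba1c", tuple(np.linspace(5, 14, 10))),
    "duration": DiscretizationScheme("duration", tuple(np.linspace(0.5, 30, 11))),
    "map": DiscretizationScheme("map", tuple(np.linspace(70, 135, 9))),
    "aer": DiscretizationScheme("aer", tuple(np.geomspace(2, 300, 11))),
}
structure = {
    "retinopathy": ["hba1c", "duration", "aer"],
    "microalbuminuria": ["hba1c", "map"],
}

cohort = generate_cohort(default_config(n_patients=6000, seed=20))
net = learn_network(cohort, schemes, structure)

cpt = net.cpts["microalbuminuria"]
print("a slice of the microalbuminuria CPT (HbA1c bin, MAP bin -> P(yes)):")
for combo, p in list(cpt.rows.items())[:4]:
    print(f"  {combo[0]:12s} {combo[1]:14s} {p:6.1%}")

patient = [
    FactorObservation("hba1c", 7.8),
    FactorObservation("duration", 8.0),
    FactorObservation("aer", 21.0),
    FactorObservation("map", 100.0),
]
print("\nfully observed patient (HbA1c 7.8, duration 8y, AER 21, MAP 100):")
for comp, p in infer(net, patient).items():
    print(f"  P({comp} = yes) = {p:.1%}")

partial = [FactorObservation("hba1c", 11.5)]
print("\nsame query knowing only HbA1c 11.5% (other factors marginalised):")
for comp, p in infer(net, partial).items():
    print(f"  P({comp} = yes) = {p:.1%}")
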