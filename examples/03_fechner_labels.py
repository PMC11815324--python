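"""Derive Fechner-adjusted SVR target labels from applied forces.

Log-transform the applied forces per level, take the reciprocal of adjacent
log-mean gaps as label spacings, and anchor the cumulative sums. Levels that
are closer in log-force (harder to discriminate) end up farther apart as
regression targets.
"""

import numpy as np

from gripdecode import build_labels, compute_label_distances, labels_from_forces

rng = np.random.default_rng(0)
forces_by_level = [
    np.exp(rng.normal(np.log(mu), 0.1, size=200)) for mu in (0.12, 0.37, 0.62, 0.87)
]
mu_log, distances = compute_label_distances(forces_by_level)
print("mean log applied force per level:", np.round(mu_log, 3))
print("label spacings 1/|mu_i - mu_i+1|:", np.round(distances, 2))

scheme = labels_from_forces(forces_by_level)
print("zero-mean labels:", np.round(scheme.labels, 2))

printed = build_labels((0.92, 1.94, 2.97), anchor_mode="first_at", anchor_value=-1.5)
print("with spacings (0.92, 1.94, 2.97) anchored at -1.5:", np.round(printed.labels, 2))
print("Spacings grow with level: log-compression packs high forces together, "
      "so their labels are spread apart to match perceived difficulty.")
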