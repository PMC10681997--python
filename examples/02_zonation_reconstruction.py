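"""Place fragments on the central-portal lobule axis from landmark genes.

The zonation coordinate ZC = pLM/(pLM + cLM) is computed from portal and
central landmark-gene sums in each fragment's liver endothelial cells,
rescaled to [0, 1], and binned into lobule layers L1..L10.
"""

import warnings

from scipy.stats import spearmanr

from fragseq.simulate import (
    LobuleSimConfig,
    simulate_landmark_panel,
    simulate_lobule_experiment,
)
from fragseq.zonation import (
    bin_layers,
    compute_zc,
    filter_landmarks,
    fragment_pseudobulk,
    group_zone,
)

warnings.filterwarnings("ignore")

cfg = LobuleSimConfig(n_fragments=200, seed=1)
exp, truth = simulate_lobule_experiment(cfg)

panel = filter_landmarks(simulate_landmark_panel(cfg))
pseudobulk = fragment_pseudobulk(exp, "LEC", min_cells=5)
result = group_zone(bin_layers(compute_zc(pseudobulk, panel)))

rho = spearmanr(result["zc_rescaled"], truth.zc.loc[result.index]).statistic
print(f"fragments placed: {len(result)} (>=5 LECs each)")
print(f"Spearman(ZC_est, ZC_true) = {rho:.3f}")
print("fragments per zone:", result["zone"].value_counts().to_dict())
print(result[["zc_raw", "zc_rescaled", "layer", "zone"]].head(5).round(3))
# rho >= 0.9 means the landmark reconstruction orders fragments along the
# lobule axis nearly as well as the (normally unobservable) truth
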