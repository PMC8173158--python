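"""Select aging and per-disease CpG markers and evaluate the predictors.

ReliefF ranks all sites; the top-k prefix (k swept under stratified CV)
defines each marker set; boosted depth-2 trees are the classifiers.
Prints the selected dimensions, held-out accuracy and AUC of the aging
predictor, and how many planted markers were recovered.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))
from analysis._common import run_through  # noqa: E402


def main() -> None:
    cfg, art = run_through("markers")
    truth = art["truth"]
    aging = art["aging_markers"]
    print(f"aging predictor: selected k = {aging.selected_k} "
          f"(CV accuracy {aging.cv_accuracy_by_k[aging.selected_k]:.3f})")
    hit = len(set(aging.selected_site_ids) & set(truth.aging_marker_ids))
    print(f"planted aging markers recovered: {hit}/{len(truth.aging_marker_ids)}")
    ev = art["aging_eval"]
    print(f"held-out aging accuracy {ev['accuracy']:.3f}, AUC {ev['auc']:.3f}")
    for d, ms in art["disease_markers"].items():
        hit = len(set(ms.selected_site_ids) & set(truth.disease_marker_ids[d]))
        print(f"{d}: selected k = {ms.selected_k}, planted recovered {hit}/"
              f"{len(truth.disease_marker_ids[d])}")
    print(f"artifacts in {cfg.out_dir}")


if __name__ == "__main__":
    main()
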