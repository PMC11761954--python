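"""End-to-end synthetic experiments: learnability, null-safety, MIL gain.

These drive the whole pipeline — generate a cohort, train the patch model,
encode, train the bag meta-model, evaluate on held-out cases — at a scale
one CPU handles in minutes. They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluate import binary_metrics
from .glisp_p import GlispPConfig, TrainConfig, split_cases, train_glisp_p
from .glisp_w import GlispWConfig, WTrainConfig, predict_slide, train_glisp_w
from .labels import GeneLabelTable
from .synthdata import SynthConfig, generate_cohort

log = logging.getLogger(__name__)


def two_stage_experiment(
    seed: int = 0,
    n_cases: int = 200,
    patches_per_slide: int = 40,
    effect_size: float = 2.0,
    witness_rate: float = 1.0,
    epochs: int = 5,
    test_fraction: float = 0.3,
    w_epochs: int = 60,
    n_slide_draws: int = 8,
    task: str = "idh",
) -> dict:
    """Train both stages on a synthetic cohort; report held-out AUCs.

    The split is case-level and stratified; the patch model never sees the
    held-out cases, and the bag model is trained on the frozen patch
    encodings of the training cases only. Returns patch-level and
    slide/case-level AUCs plus witness/background attention statistics.
    """
    ss = np.random.SeedSequence(seed)
    s_cohort, s_split, s_train_p, s_train_w, s_draw = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]

    cohort = generate_cohort(SynthConfig(
        n_cases=n_cases, patches_per_slide=patches_per_slide,
        effect_size=effect_size, witness_rate=witness_rate, seed=s_cohort))
    labels, manifest, images = cohort.labels, cohort.manifest, cohort.images
    status = labels.for_task(task)

    split_rng = np.random.default_rng(s_split)
    train_cases, test_cases = split_cases(manifest["case_id"].to_numpy(),
                                          status.to_dict(), test_fraction, split_rng)
    tr_mask = manifest["case_id"].isin(train_cases).to_numpy()
    te_mask = manifest["case_id"].isin(test_cases).to_numpy()

    model_p, hist_p = train_glisp_p(
        images[tr_mask], manifest[tr_mask].reset_index(drop=True), labels, task,
        config=TrainConfig(max_epochs=epochs, seed=s_train_p))

    patch_probs = model_p.predict_proba(images[te_mask])
    y_patch = status.loc[manifest["case_id"][te_mask]].to_numpy()
    patch = binary_metrics(patch_probs, y_patch)

    encodings = model_p.encode(images)
    slide_ids = manifest["slide_id"].unique()
    slide_enc = {s: encodings[(manifest["slide_id"] == s).to_numpy()] for s in slide_ids}
    slide_cases = dict(manifest[["slide_id", "case_id"]].drop_duplicates()
                       .itertuples(index=False))
    train_enc = {s: e for s, e in slide_enc.items() if slide_cases[s] in train_cases}

    model_w, hist_w = train_glisp_w(
        train_enc, slide_cases, labels, task,
        config=WTrainConfig(max_epochs=w_epochs, seed=s_train_w))

    draw_rng = np.random.default_rng(s_draw)
    bag_probs, y_bag = [], []
    for s in slide_ids:
        if slide_cases[s] not in test_cases:
            continue
        bag_probs.append(predict_slide(model_w, slide_enc[s], n_draws=n_slide_draws,
                                       seed=int(draw_rng.integers(2**31))))
        y_bag.append(int(status.loc[slide_cases[s]]))
    bag = binary_metrics(bag_probs, y_bag)

    # attention on witness vs background patches of positive held-out slides
    wit_w, bg_w = attention_witness_gap(model_w, cohort, slide_enc,
                                        test_cases, seed=s_draw)

    return {
        "patch_auc": patch["roc_auc"],
        "bag_auc": bag["roc_auc"],
        "patch_metrics": patch,
        "bag_metrics": bag,
        "witness_attention": wit_w,
        "background_attention": bg_w,
        "history_p": hist_p,
        "history_w": hist_w,
        "n_patches_train": int(tr_mask.sum()),
        "n_patches_test": int(te_mask.sum()),
        "n_cases": n_cases,
        "n_cases_test": len(test_cases),
    }


def attention_witness_gap(model_w, cohort, slide_enc, case_subset,
                          seed: int = 0, max_bags: int = 100) -> tuple[list, list]:
    """Mean attention weights on witness vs background members of positive bags."""
    from .tiling import sample_bag

    rng = np.random.default_rng(seed)
    truth = cohort.truth
    wit_weights: list[float] = []
    bg_weights: list[float] = []
    n_bags = 0
    for s, enc in slide_enc.items():
        rows = truth[truth["slide_id"] == s]
        if rows.empty or rows["case_status"].iloc[0] != 1:
            continue
        if case_subset is not None and rows["case_id"].iloc[0] not in case_subset:
            continue
        flags = rows["witness"].to_numpy()
        if flags.all() or not flags.any():
            continue
        bag = sample_bag(list(range(len(enc))), k=model_w.bag_size,
                         seed=int(rng.integers(2**31)))
        _, a = model_w.forward_bag(enc[bag.members])
        member_flags = flags[bag.members]
        if member_flags.any():
            wit_weights.append(float(a[member_flags].mean()))
        if (~member_flags).any():
            bg_weights.append(float(a[~member_flags].mean()))
        n_bags += 1
        if n_bags >= max_bags:
            break
    return wit_weights, bg_weights


def null_experiment(seed: int = 0, n_cases: int = 400, patches_per_slide: int = 20,
                    epochs: int = 5, test_fraction: float = 0.5) -> dict:
    """Effect-size-zero control: AUCs should hover around chance.

    The held-out half (200 cases) keeps the sampling error of a chance-level
    bag AUC small enough that [0.40, 0.60] is a ~2.5-sigma band.
    """
    return two_stage_experiment(seed=seed, n_cases=n_cases,
                                patches_per_slide=patches_per_slide,
                                effect_size=0.0, epochs=epochs,
                                test_fraction=test_fraction)
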