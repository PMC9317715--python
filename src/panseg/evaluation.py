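"""Evaluation: Dice coefficients, cross-validation and failure diagnostics.

Per-class Dice Sørensen coefficients (DSC = 2TP / (2TP + FP + FN)) are
computed over pancreas voxels, treating one subregion as positive and the
other two as negative.  The "overall" score is the unweighted mean of the
three class DSCs (a voxel-weighted variant is available behind a flag).
Diagnostics mirror the two failure modes that matter anatomically: the
fraction of errors concentrated at the body/tail border, and direct
head<->tail confusions (which a sound model should never produce, since
head and tail are not adjacent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import bayes as bayes_mod
from . import mask_geometry, net
from .io_prep import BODY, CONN26, HEAD, SUBREGION_NAMES, SUBREGIONS, TAIL


def dsc(pred, ref, cls, mask=None):
    """Dice coefficient for one subregion class, as a fraction in [0, 1].

    Computed over pancreas voxels only (``mask`` defaults to the union of
    nonzero labels).  Both sets empty -> 1.0 by convention.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    if mask is None:
        mask = (pred > 0) | (ref > 0)
    p = pred[mask] == cls
    r = ref[mask] == cls
    denom = p.sum() + r.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, r).sum() / denom)


def dsc_percentages(pred, ref, mask=None, voxel_weighted=False):
    """(head, body, tail, overall) DSC as percentages."""
    per_class = np.array([dsc(pred, ref, s, mask) for s in SUBREGIONS]) * 100.0
    if voxel_weighted:
        ref = np.asarray(ref)
        w = np.array([np.sum(ref == s) for s in SUBREGIONS], dtype=float)
        overall = float(np.average(per_class, weights=w)) if w.sum() else float(
            per_class.mean())
    else:
        overall = float(per_class.mean())
    return per_class[0], per_class[1], per_class[2], overall


def crossval_split(case_ids, folds=4, seed=0):
    """Deterministic balanced k-fold partition of case ids.

    Subset sizes differ by at most 1; every case is tested exactly once.
    Returns a list of (train_ids, test_ids) tuples.
    """
    case_ids = list(case_ids)
    if len(case_ids) < folds:
        raise ValueError(f"need at least {folds} cases for {folds} folds")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    subsets = [order[i::folds] for i in range(folds)]
    splits = []
    for i in range(folds):
        test = list(subsets[i])
        train = [c for j, s in enumerate(subsets) if j != i for c in s]
        splits.append((train, test))
    return splits


def _bt_interface(ref):
    """Reference voxels on the body/tail border (either side)."""
    ref = np.asarray(ref)
    body, tail = ref == BODY, ref == TAIL
    near_tail = ndimage.binary_dilation(tail, structure=CONN26)
    near_body = ndimage.binary_dilation(body, structure=CONN26)
    return (body & near_tail) | (tail & near_body)


def _error_counts(pred, ref, mask=None, border_width=3):
    """(n_border_errors, n_errors, head_tail_confusions) for one case."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    if mask is None:
        mask = ref > 0
    mask = np.asarray(mask).astype(bool)
    errors = mask & (pred != ref)
    confusions = int(np.sum(((ref == HEAD) & (pred == TAIL))
                            | ((ref == TAIL) & (pred == HEAD))))
    n_err = int(errors.sum())
    if n_err == 0:
        return 0, 0, confusions
    interface = _bt_interface(ref) & mask
    if interface.any():
        dist = mask_geometry.geodesic_distance_map(
            mask, np.argwhere(interface), spacing=(1.0, 1.0, 1.0)
        )
        zone = mask & (dist <= border_width)
    else:
        zone = np.zeros_like(mask)
    return int(np.sum(errors & zone)), n_err, confusions


def failure_diagnostics(pred, ref, mask=None, border_width=3):
    """(boundary_error_fraction, head_tail_confusions).

    boundary_error_fraction: misclassified voxels within ``border_width``
    voxels (geodesic, inside the mask) of the reference body/tail
    interface, divided by all misclassified voxels; ``None`` when there
    are no errors.  head_tail_confusions: count of voxels labelled head in
    one volume and tail in the other.
    """
    n_border, n_err, confusions = _error_counts(pred, ref, mask, border_width)
    if n_err == 0:
        return None, confusions
    return n_border / n_err, confusions


@dataclass
class EvalReport:
    """Per-class and overall DSC (percent) plus failure diagnostics."""

    dsc_head: float
    dsc_body: float
    dsc_tail: float
    overall: float
    per_case: pd.DataFrame
    boundary_error_fraction: float | None
    head_tail_confusions: int
    model: str = "proposed"

    def to_dict(self):
        return {
            "model": self.model,
            "dsc_head": self.dsc_head,
            "dsc_body": self.dsc_body,
            "dsc_tail": self.dsc_tail,
            "overall": self.overall,
            "boundary_error_fraction": self.boundary_error_fraction,
            "head_tail_confusions": self.head_tail_confusions,
        }

    def to_csv(self, path):
        self.per_case.to_csv(path, index=False)

    def __str__(self):
        return (f"[{self.model}] DSC%% head {self.dsc_head:.1f} body "
                f"{self.dsc_body:.1f} tail {self.dsc_tail:.1f} "
                f"overall {self.overall:.1f}")


def build_report(predictions, references, masks, case_ids, model="proposed",
                 voxel_weighted=False):
    """Aggregate per-case predictions into an EvalReport.

    Class DSCs are averaged over cases; diagnostics pool errors over all
    cases (fraction of pooled errors near the body/tail border).
    """
    rows = []
    n_border = n_err_total = confusions = 0
    for pred, ref, mask, cid in zip(predictions, references, masks, case_ids):
        h, b, t, o = dsc_percentages(pred, ref, mask, voxel_weighted)
        nb, n_err, conf = _error_counts(pred, ref, mask)
        n_border += nb
        n_err_total += n_err
        confusions += conf
        rows.append({"case_id": cid, "dsc_head": h, "dsc_body": b,
                     "dsc_tail": t, "overall": o, "n_errors": n_err})
    table = pd.DataFrame(rows)
    pooled_frac = (n_border / n_err_total) if n_err_total else None
    return EvalReport(
        dsc_head=float(table["dsc_head"].mean()),
        dsc_body=float(table["dsc_body"].mean()),
        dsc_tail=float(table["dsc_tail"].mean()),
        overall=float(table["overall"].mean()),
        per_case=table,
        boundary_error_fraction=pooled_frac,
        head_tail_confusions=confusions,
        model=model,
    )


# ----------------------------------------------------------------------
# full pipeline evaluation
# ----------------------------------------------------------------------

@dataclass
class EvalCase:
    """A preprocessed case: id, normalized/cropped volume, reference labels."""

    case_id: str
    vol: object
    labels: np.ndarray


@dataclass
class FoldResult:
    fold: int
    test_ids: list
    bayes_report: EvalReport
    fused_report: EvalReport
    plain_report: EvalReport | None
    gaussians: bayes_mod.ClassGaussians
    train_state: net.TrainState


def _guard_no_leakage(train_ids, test_ids):
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise RuntimeError(f"data leakage: case(s) {sorted(overlap)} in both "
                           "training and test sets")


def _case_features(case, supervised, feature_kwargs):
    labels = case.labels if supervised else None
    return mask_geometry.compute_features(case.vol.mask, labels,
                                          spacing=case.vol.spacing,
                                          **feature_kwargs)


def evaluate_pipeline(cases, mode="crossval", folds=4, seed=0,
                      net_config=None, sigma_floor=bayes_mod.SIGMA_FLOOR,
                      pretrained=None, ablation=False, feature_kwargs=None,
                      train_net=True):
    """Run the full pipeline in cross-validation or external-validation mode.

    crossval: per fold, Bayes Gaussians are fitted and the network trained
    on fold-train cases only (a leakage guard aborts on any overlap), then
    the fold-test cases are segmented three ways: Bayes-only argmax, the
    fused network, and (with ``ablation``) a plain network trained without
    anatomical input or fusion.

    external: no parameter is updated; ``pretrained`` supplies
    ``(ClassGaussians, UNet3D)`` and every case is a test case.

    Training-side features use reference labels to locate the head
    endpoint (supervised mode); test-side features never see labels.
    Returns a list of FoldResult.
    """
    feature_kwargs = feature_kwargs or {}
    if net_config is None:
        net_config = net.NetConfig.desk_test(seed=seed)
    by_id = {c.case_id: c for c in cases}
    feats_train = {c.case_id: _case_features(c, True, feature_kwargs) for c in cases}
    feats_test = {c.case_id: _case_features(c, False, feature_kwargs) for c in cases}

    if mode == "external":
        if pretrained is None:
            raise ValueError("external mode requires a pretrained (gaussians, model)")
        gaussians, model = pretrained
        splits = [([], [c.case_id for c in cases])]
    elif mode == "crossval":
        splits = crossval_split([c.case_id for c in cases], folds=folds, seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    results = []
    for fold, (train_ids, test_ids) in enumerate(splits):
        if mode == "crossval":
            _guard_no_leakage(train_ids, test_ids)
            gaussians = bayes_mod.fit_gaussians(
                [feats_train[i] for i in train_ids],
                [by_id[i].labels for i in train_ids],
                sigma_floor=sigma_floor,
            )
        X_test = {i: bayes_mod.posterior_map(feats_test[i], gaussians)
                  for i in test_ids}
        model = None
        plain_model = None
        train_state = net.TrainState()
        if mode == "crossval" and train_net:
            X_train = {i: bayes_mod.posterior_map(feats_train[i], gaussians)
                       for i in train_ids}
            dataset = [(by_id[i].vol, by_id[i].labels, X_train[i])
                       for i in train_ids]
            model, train_state = net.train(dataset, net_config)
            if ablation:
                plain_cfg = replace(net_config, use_bayes_input=False, fuse=False)
                plain_dataset = [(by_id[i].vol, by_id[i].labels, None)
                                 for i in train_ids]
                plain_model, _ = net.train(plain_dataset, plain_cfg)
        elif mode == "external":
            model = pretrained[1]

        refs = [by_id[i].labels for i in test_ids]
        masks = [by_id[i].vol.mask for i in test_ids]
        bayes_preds = [bayes_mod.bayes_segment(X_test[i], by_id[i].vol.mask)
                       for i in test_ids]
        bayes_report = build_report(bayes_preds, refs, masks, test_ids,
                                    model="bayes-only")
        fused_report = None
        plain_report = None
        if model is not None:
            fused_preds = [net.predict(model, by_id[i].vol, X_test[i])[1]
                           for i in test_ids]
            fused_report = build_report(fused_preds, refs, masks, test_ids,
                                        model="proposed")
        if plain_model is not None:
            plain_preds = [net.predict(plain_model, by_id[i].vol, None)[1]
                           for i in test_ids]
            plain_report = build_report(plain_preds, refs, masks, test_ids,
                                        model="net-only")
        results.append(FoldResult(fold=fold, test_ids=list(test_ids),
                                  bayes_report=bayes_report,
                                  fused_report=fused_report,
                                  plain_report=plain_report,
                                  gaussians=gaussians,
                                  train_state=train_state))
    return results


def pooled_summary(results):
    """Mean DSCs over folds, per model, as a tidy DataFrame (percent)."""
    rows = []
    for res in results:
        for rep in (res.bayes_report, res.fused_report, res.plain_report):
            if rep is None:
                continue
            d = rep.to_dict()
            d["fold"] = res.fold
            rows.append(d)
    df = pd.DataFrame(rows)
    return (df.groupby("model")[["dsc_head", "dsc_body", "dsc_tail", "overall"]]
            .mean().reset_index())
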