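"""Study harnesses on synthetic cohorts.

The inter-slice-distance (ISD) reproducibility study runs a virtual observer
twice per volume at each ISD and summarizes bifurcation-localization
distance, pooled slice-wise DSC/HD per boundary and branch, paired tests of
DSC across ISD settings, and intraclass correlation of vessel-wall volume
and pooled vessel-wall-thickness map cells.

The partition study trains one segmentation network under each of two data-
partition schemes - patient-based (half the patients contribute both
timepoints to training) and time-based (all baseline volumes train the
network that segments follow-up volumes) - with an identical test set, and
compares stratified accuracy, paired per-slice DSC, and VWV/VWT agreement
against the manual-style reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics, quantify, segnet, stats
from .phantom import ObserverModel, PhantomCase, virtual_observer

log = logging.getLogger(__name__)

Key = Tuple[int, str]


@dataclass
class PartitionPlan:
    scheme: str  # "patient_based" | "time_based"
    train: List[Key]
    validation: List[Key]
    test: List[Key]

    def all_keys(self) -> List[Key]:
        return self.train + self.validation + self.test


def make_partition(patient_ids: Sequence[int], scheme: str,
                   seed: int = 0) -> PartitionPlan:
    """Assign (patient, timepoint) volumes to train/validation/test.

    patient-based: one half of the patients contributes baseline AND
    follow-up volumes to training; the other half's baselines validate and
    its follow-ups test. time-based: every baseline trains; the follow-ups
    are split into validation and test. The test set (second half's
    follow-ups) is identical across the two schemes for the same seed.
    """
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 patients to partition")
    if scheme not in ("patient_based", "time_based"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    ids = [ids[i] for i in rng.permutation(len(ids))]
    half_a, half_b = ids[:len(ids) // 2], ids[len(ids) // 2:]
    test = [(p, "followup") for p in half_b]
    if scheme == "patient_based":
        train = [(p, tp) for p in half_a for tp in ("baseline", "followup")]
        val = [(p, "baseline") for p in half_b]
    else:
        train = [(p, "baseline") for p in half_a + half_b]
        val = [(p, "followup") for p in half_a]
    return PartitionPlan(scheme=scheme, train=sorted(train),
                         validation=sorted(val), test=sorted(test))


# ---------------------------------------------------------------------------
# ISD reproducibility study
# ---------------------------------------------------------------------------

@dataclass
class ISDStudyReport:
    bifurcation: pd.DataFrame     # per-ISD bifurcation-distance summary
    pooled: pd.DataFrame          # DSC/HD per ISD x boundary x branch
    paired_tests: pd.DataFrame    # DSC tests across ISD pairs
    icc: pd.DataFrame             # ICC of VWV and pooled VWT cells per ISD
    per_slice: pd.DataFrame       # raw slice comparisons


def run_isd_study(cases: Sequence[PhantomCase],
                  isds: Sequence[float] = (1.0, 2.0, 3.0),
                  observer: Optional[ObserverModel] = None,
                  n_trials: int = 2, vz: float = 0.35,
                  grid_spacing: float = 0.1) -> ISDStudyReport:
    """Repeated virtual-observer segmentation and reproducibility summary."""
    observer = observer or ObserverModel()
    rows_bif, slice_rows = [], []
    vwv_by_isd: Dict[float, np.ndarray] = {}
    vwt_by_isd: Dict[float, np.ndarray] = {}
    for isd in isds:
        vwvs = np.zeros((len(cases), n_trials))
        vwt_cells: List[np.ndarray] = []
        for vi, case in enumerate(cases):
            trials = [virtual_observer(case, isd, observer,
                                       trial_seed=1000 * vi + t)
                      for t in range(n_trials)]
            for t1, t2 in combinations(range(n_trials), 2):
                rows_bif.append({
                    "isd": isd, "volume": vi,
                    "distance": metrics.bifurcation_distance(
                        trials[t1], trials[t2])})
                comps = metrics.compare_stacks(trials[t1], trials[t2],
                                               vz=vz,
                                               grid_spacing=grid_spacing)
                slice_rows.append(metrics.comparisons_frame(
                    comps, isd=isd, volume=vi))
            for t, st in enumerate(trials):
                vwvs[vi, t] = quantify.vwv(st, grid_spacing=grid_spacing)
            maps = [quantify.vwt_map(st, grid_spacing=grid_spacing)
                    for st in trials[:2]]
            a, b = quantify.map_difference(maps[0], maps[1])
            vwt_cells.append(np.column_stack([a, b]))
        vwv_by_isd[isd] = vwvs
        vwt_by_isd[isd] = np.vstack(vwt_cells)

    per_slice = pd.concat(slice_rows, ignore_index=True)
    bif = pd.DataFrame(rows_bif)
    bif_summary = bif.groupby("isd")["distance"].agg(
        ["mean", "std", "max"]).reset_index()

    pooled_rows = []
    for isd in isds:
        sub_isd = per_slice[per_slice.isd == isd]
        for kind in ("MAB", "LIB"):
            for branch in ("CCA", "ICA", "ALL"):
                sub = sub_isd[sub_isd.boundary_kind == kind]
                if branch != "ALL":
                    sub = sub[sub.vessel == branch]
                pooled_rows.append({
                    "isd": isd, "boundary": kind, "branch": branch,
                    "n_slices": len(sub),
                    "dsc_mean": sub.dsc.mean(), "dsc_sd": sub.dsc.std(ddof=1),
                    "hd_mean": sub.hd.mean(), "hd_sd": sub.hd.std(ddof=1)})
    pooled = pd.DataFrame(pooled_rows)

    test_rows = []
    for isd_a, isd_b in combinations(isds, 2):
        for kind in ("MAB", "LIB"):
            for branch in ("CCA", "ICA", "ALL"):
                x, y = _paired_dsc(per_slice, isd_a, isd_b, kind, branch)
                if len(x) < 3:
                    continue
                try:
                    name, p = stats.normality_gated_paired_test(x, y)
                except stats.DegenerateSampleError:
                    name, p = "degenerate", np.nan
                test_rows.append({"isd_pair": f"{isd_a:g}-{isd_b:g}",
                                  "boundary": kind, "branch": branch,
                                  "n": len(x), "test": name, "p": p})
    paired_tests = pd.DataFrame(test_rows)

    icc_rows = []
    for isd in isds:
        r = stats.icc_absolute_agreement(vwv_by_isd[isd])
        icc_rows.append({"isd": isd, "measurement": "VWV", "icc": r.icc,
                         "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                         "n": r.n_subjects})
        r = stats.icc_absolute_agreement(vwt_by_isd[isd])
        icc_rows.append({"isd": isd, "measurement": "VWT", "icc": r.icc,
                         "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                         "n": r.n_subjects})
    icc = pd.DataFrame(icc_rows)
    return ISDStudyReport(bifurcation=bif_summary, pooled=pooled,
                          paired_tests=paired_tests, icc=icc,
                          per_slice=per_slice)


def _paired_dsc(per_slice: pd.DataFrame, isd_a: float, isd_b: float,
                kind: str, branch: str) -> Tuple[np.ndarray, np.ndarray]:
    """Pair per-slice DSC of two ISD conditions on common (volume, z)."""
    sel = per_slice.boundary_kind == kind
    if branch != "ALL":
        sel = sel & (per_slice.vessel == branch)
    a = per_slice[sel & (per_slice.isd == isd_a)]
    b = per_slice[sel & (per_slice.isd == isd_b)]
    a = a.assign(zz=a.z.round(4)).set_index(["volume", "zz"])
    b = b.assign(zz=b.z.round(4)).set_index(["volume", "zz"])
    common = a.index.intersection(b.index)
    return (a.loc[common].dsc.to_numpy(),
            b.loc[common].dsc.to_numpy())


# ---------------------------------------------------------------------------
# partition study
# ---------------------------------------------------------------------------

@dataclass
class PartitionStudyReport:
    plans: Dict[str, PartitionPlan]
    stratified: Dict[str, pd.DataFrame]
    paired_tests: pd.DataFrame
    agreement: pd.DataFrame       # VWV/VWT vs manual per scheme
    per_slice: pd.DataFrame
    missing: Dict[str, List[float]] = field(default_factory=dict)
    mean_test_dsc: Dict[str, float] = field(default_factory=dict)


def run_partition_study(cohort: Sequence[Tuple[PhantomCase, PhantomCase]],
                        train_config: Optional[segnet.TrainConfig] = None,
                        seed: int = 0, isd: float = 2.0,
                        sample_step: Optional[float] = None,
                        vz: float = 0.35,
                        grid_spacing: float = 0.1,
                        models: Optional[dict] = None,
                        quantify_measurements: bool = True
                        ) -> PartitionStudyReport:
    """Train under both partition schemes and evaluate on the shared test set.

    ``sample_step`` is the longitudinal spacing of the training slices
    (defaults to the working ISD; the augmentation reslice step in
    ``train_config`` is applied on top via random geometric augmentation).
    ``models`` may inject pre-built models per scheme (e.g. an oracle) to
    exercise the harness without training. ``vz`` sets the common comparison
    grid; ``quantify_measurements=False`` skips the VWV/VWT agreement block
    (used by quick directional checks that only need DSC).
    """
    train_config = train_config or segnet.TrainConfig()
    cases: Dict[Key, PhantomCase] = {}
    for base, fu in cohort:
        cases[base.key] = base
        cases[fu.key] = fu
    ids = sorted({k[0] for k in cases})
    plans = {s: make_partition(ids, s, seed=seed)
             for s in ("patient_based", "time_based")}
    assert plans["patient_based"].test == plans["time_based"].test
    step = sample_step if sample_step is not None else isd

    slice_rows, missing = [], {}
    strat, mean_dsc = {}, {}
    agree_rows = []
    for scheme, plan in plans.items():
        if models and scheme in models:
            model = models[scheme]
        else:
            samples = []
            for key in plan.train:
                samples += segnet.slide_samples_from_case(
                    cases[key], step=step,
                    shape=train_config.input_shape)
            samples = segnet.augment_training_set(
                samples, flip_h=train_config.flip_h,
                flip_v=train_config.flip_v,
                n_random=train_config.n_random_augment,
                seed=train_config.seed)
            log.info("%s: training on %d slices", scheme, len(samples))
            model = segnet.train(samples, train_config).model
        missing[scheme] = []
        vwv_auto, vwv_man, vwt_auto, vwt_man = [], [], [], []
        for key in plan.test:
            case = cases[key]
            manual = case.geometry.truth_stack(isd,
                                               z_limits=case.volume.z_range)
            boxes = segnet.ica_end_boxes_from_truth(case, isd=isd)
            res = segnet.segment_volume(
                model, case.volume, case.bifurcation_z,
                ica_end_boxes=boxes, isd=isd,
                input_shape=train_config.input_shape)
            missing[scheme] += res.missing
            if len(res.stack.contours) < 2:
                log.warning("%s: test case %s produced no usable stack",
                            scheme, key)
                continue
            try:
                comps = metrics.compare_stacks(manual, res.stack, vz=vz,
                                               grid_spacing=grid_spacing)
                slice_rows.append(metrics.comparisons_frame(
                    comps, scheme=scheme, volume=key[0]))
            except ValueError as exc:
                log.warning("%s: comparison failed for %s: %s",
                            scheme, key, exc)
                continue
            if not quantify_measurements:
                continue
            try:
                va = quantify.vwv(res.stack, grid_spacing=grid_spacing)
                vm = quantify.vwv(manual, grid_spacing=grid_spacing)
                vwv_auto.append(va)
                vwv_man.append(vm)
                m_auto = quantify.vwt_map(res.stack,
                                          grid_spacing=grid_spacing)
                m_man = quantify.vwt_map(manual, grid_spacing=grid_spacing)
                a, m = quantify.map_difference(m_man, m_auto)
                vwt_auto.append(float(m.mean()))
                vwt_man.append(float(a.mean()))
            except ValueError as exc:
                log.warning("%s: quantification failed for %s: %s",
                            scheme, key, exc)
        agree_rows += _agreement_rows(scheme, "VWV", vwv_auto, vwv_man)
        agree_rows += _agreement_rows(scheme, "VWT", vwt_auto, vwt_man)

    per_slice = pd.concat(slice_rows, ignore_index=True) if slice_rows \
        else pd.DataFrame(columns=["scheme", "volume", "z", "boundary_kind",
                                   "vessel", "dsc", "hd"])
    for scheme in plans:
        sub = per_slice[per_slice.scheme == scheme]
        strat[scheme] = metrics.stratify_frame(sub) if len(sub) else \
            pd.DataFrame()
        mab = sub[sub.boundary_kind == "MAB"]
        mean_dsc[scheme] = float(mab.dsc.mean()) if len(mab) else np.nan

    test_rows = []
    for kind in ("MAB", "LIB"):
        for branch in ("CCA", "ICA", "ALL"):
            x, y = _paired_scheme_dsc(per_slice, kind, branch)
            if len(x) < 3:
                continue
            try:
                name, p = stats.normality_gated_paired_test(x, y)
            except stats.DegenerateSampleError:
                name, p = "degenerate", np.nan
            test_rows.append({"boundary": kind, "branch": branch,
                              "n": len(x), "test": name, "p": p,
                              "mean_patient_based": float(np.mean(x)),
                              "mean_time_based": float(np.mean(y))})
    return PartitionStudyReport(
        plans=plans, stratified=strat,
        paired_tests=pd.DataFrame(test_rows),
        agreement=pd.DataFrame(agree_rows),
        per_slice=per_slice, missing=missing, mean_test_dsc=mean_dsc)


def _agreement_rows(scheme: str, name: str, auto: list, manual: list):
    if len(auto) < 2:
        return []
    d_mean, d_sd, ad_mean, ad_sd = stats.delta_summary(auto, manual)
    row = {"scheme": scheme, "measurement": name, "n": len(auto),
           "delta_mean": d_mean, "delta_sd": d_sd,
           "abs_delta_mean": ad_mean, "abs_delta_sd": ad_sd}
    try:
        r, p = stats.pearson(manual, auto)
        row.update(pearson_r=r, pearson_p=p)
    except (ValueError, stats.DegenerateSampleError):
        row.update(pearson_r=np.nan, pearson_p=np.nan)
    ba = stats.bland_altman(manual, auto)
    row.update(bias=ba.bias, rpc=ba.rpc, cv=ba.cv)
    return [row]


def _paired_scheme_dsc(per_slice: pd.DataFrame, kind: str,
                       branch: str) -> Tuple[np.ndarray, np.ndarray]:
    sel = per_slice.boundary_kind == kind
    if branch != "ALL":
        sel = sel & (per_slice.vessel == branch)
    a = per_slice[sel & (per_slice.scheme == "patient_based")]
    b = per_slice[sel & (per_slice.scheme == "time_based")]
    a = a.assign(zz=a.z.round(4)).set_index(["volume", "zz"])
    b = b.assign(zz=b.z.round(4)).set_index(["volume", "zz"])
    common = a.index.intersection(b.index)
    return (a.loc[common].dsc.to_numpy(), b.loc[common].dsc.to_numpy())
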