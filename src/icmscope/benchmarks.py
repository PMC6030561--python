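"""Reproducible synthetic benchmarks of the full analysis chain.

Each function simulates the study conditions with the scene generator, runs
the complete pipeline on the rendered images, and measures how well the
known ground truth is recovered — parameter recovery of the localization
model, polar-proximity and length/count properties, population
classification, segmentation quality, the content–fluorescence correlation,
the parsimony oracle, and registration accuracy.  All randomness is driven
by a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .imgio import estimate_distortion
from .phylo import (
    attach_traits,
    brute_force_min_changes,
    clade_leafset,
    fitch_parsimony,
    mp_labelings,
    random_trait_tree,
    read_newick,
    root_state_set,
)
from .pipeline import analyze_field, match_cells
from .popstats import (
    BChlMeasurement,
    classify_localization,
    foci_count_length_table,
    intensity_content_correlation,
    old_new_intensity_compare,
    pole_distance_stats,
    spacing_pairs,
    spacing_regression,
)
from .synthetic import LocalizationModel, SceneConfig, generate_scene

REFERENCE_MODEL = LocalizationModel(
    pattern="restricted", d_old=0.6, d_new=0.5, L_star=2.5, rho=0.6
)


def _child_seeds(seed: int, n: int) -> list:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def restricted_population_recovery(seed: int, n_cells: int = 300) -> dict:
    """Simulate a fully adhesin-marked restricted population and recover the
    localization-model parameters from the rendered images."""
    cfg = SceneConfig(n_cells=n_cells, field_shape=(2048, 2048),
                      adhesin_fraction=1.0, seed=seed)
    field_img, truth = generate_scene(cfg, REFERENCE_MODEL)
    res = analyze_field(field_img)

    dist = pole_distance_stats(res.foci, res.cells, res.calls)
    pairs = spacing_pairs(res.cells, res.foci)
    reg = spacing_regression(pairs)
    cmp_ = old_new_intensity_compare(res.cells, res.foci, res.calls)

    assigned = {c.cell_id for c in res.calls if c.old_pole != "unassigned"}
    by_cell: dict = {}
    for f in res.foci:
        by_cell.setdefault(f.cell_id, []).append(f)
    lengths = {c.id: c.length_um for c in res.cells}
    singles = [(fl[0].s_pos, lengths[cid]) for cid, fl in by_cell.items()
               if len(fl) == 1 and cid in assigned]
    old_half = float(np.mean([s < L / 2 for s, L in singles])) if singles else np.nan

    summary, _ = foci_count_length_table(res.cells, res.foci)
    med = summary.set_index("focus_class")["median_um"]

    return dict(
        n_cells=len(res.cells),
        median_old_distance_um=dist["old"]["median"],
        old_distance_cv=dist["old"]["cv"],
        median_new_distance_um=dist["new"]["median"],
        spacing_slope=reg.slope,
        spacing_intercept=reg.intercept,
        spacing_r=reg.r,
        n_pairs=reg.n,
        median_new_old_ratio=cmp_["median_ratio"],
        single_focus_old_half_fraction=old_half,
        n_single=len(singles),
        median_length_1focus=float(med.get("1", np.nan)),
        median_length_2focus=float(med.get("2", np.nan)),
    )


def segmentation_quality(seed: int, n_cells: int = 120) -> dict:
    """Cell recall/precision and length accuracy on a default-noise field."""
    cfg = SceneConfig(n_cells=n_cells, field_shape=(1280, 1280), seed=seed)
    field_img, truth = generate_scene(cfg, REFERENCE_MODEL)
    res = analyze_field(field_img)
    m = match_cells(truth, res.cells, max_dist_px=2.0)
    err = np.abs(m["length_rel_errors"])
    return dict(
        n_truth=len(truth.cells),
        n_detected=len(res.cells),
        recall=float(m["recall"]),
        precision=float(m["precision"]),
        length_within_10pct_fraction=float(np.mean(err <= 0.10)) if len(err)
        else np.nan,
    )


def classification_accuracy(seed: int, n_pops: int = 10,
                            n_cells: int = 200) -> dict:
    """Label 10 restricted + 10 nonrestricted populations; count correct."""
    seeds = _child_seeds(seed, 2 * n_pops)
    correct = total = 0
    for i, pattern in enumerate(["restricted"] * n_pops +
                                ["nonrestricted"] * n_pops):
        cfg = SceneConfig(n_cells=n_cells, field_shape=(1664, 1664),
                          seed=seeds[i])
        model = LocalizationModel(
            pattern=pattern, d_old=0.6, d_new=0.5, L_star=2.5, rho=0.6
        )
        field_img, _ = generate_scene(cfg, model)
        res = analyze_field(field_img)
        label = classify_localization(res.profiles).label
        correct += label == pattern
        total += 1
    return dict(n_correct=correct, n_total=total)


def content_correlation(seed: int, n_scenes: int = 5, n_cells: int = 60) -> dict:
    """Fluorescence amplitude ∝ assigned BChl content across cultures → r."""
    contents = np.linspace(0.2, 1.0, n_scenes)
    seeds = _child_seeds(seed + 1, n_scenes)
    means = {}
    meas = []
    for i, (content, s) in enumerate(zip(contents, seeds)):
        cfg = SceneConfig(n_cells=n_cells, field_shape=(896, 896), seed=s)
        model = LocalizationModel(
            pattern="restricted", d_old=0.6, d_new=0.5, L_star=2.5, rho=0.6,
            amp=400.0 * content,
        )
        field_img, _ = generate_scene(cfg, model)
        res = analyze_field(field_img)
        cid = f"culture{i}"
        means[cid] = float(np.mean(list(res.mean_intensities.values())))
        meas.append(BChlMeasurement(cid, A770=float(content), OD660=1.0))
    r, _ = intensity_content_correlation(meas, means)
    return dict(pearson_r=r, n=n_scenes)


def parsimony_oracle(seed: int, n_trees: int = 100, n_reroot: int = 20) -> dict:
    """Fitch vs exhaustive brute force on random trees; rerooting invariance."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trees):
        tt = random_trait_tree(rng, int(rng.integers(3, 9)),
                               int(rng.integers(2, 4)))
        fitch_parsimony(tt)
        agree += tt.min_changes == brute_force_min_changes(tt)
    invariant = 0
    for _ in range(n_reroot):
        tt = random_trait_tree(rng, int(rng.integers(4, 9)), 2)
        fitch_parsimony(tt)
        tree2 = tt.tree.clone(depth=1)
        edges = [e for e in tree2.preorder_edge_iter()
                 if e.head_node.parent_node is not None]
        tree2.reroot_at_edge(edges[int(rng.integers(len(edges)))],
                             update_bipartitions=False)
        tt2 = attach_traits(tree2, tt.leaf_states, alphabet=tt.alphabet)
        fitch_parsimony(tt2)
        invariant += tt2.min_changes == tt.min_changes
    return dict(brute_force_agreement=agree, n_trees=n_trees,
                reroot_invariant=invariant, n_reroot=n_reroot)


def curated_tree_inference() -> dict:
    """Ancestral-state inference on the curated 14-species tree fixture.

    Checks whether some maximum-parsimony labeling has a nonrestricted root
    with every gain of the restricted state inside the Rhizobiales clade.
    """
    from importlib import resources

    data = resources.files("icmscope") / "data"
    tree = read_newick((data / "pnsb_tree_curated.nwk").read_text())
    tt = attach_traits(tree, str(data / "pnsb_traits_curated.csv"),
                       alphabet=("nonrestricted", "restricted"),
                       missing_policy="exclude")
    fitch_parsimony(tt)
    rhizobiales = clade_leafset(tt, [
        "Rhodopseudomonas_palustris", "Rhodoplanes_elegans",
        "Rhodobium_orientis", "Rhodoblastus_acidophilus",
    ])
    root_key = tuple(sorted(tt.leaf_labels()))
    found = False
    for lab in mp_labelings(tt):
        if lab[root_key] != "nonrestricted":
            continue
        gains = []
        for node in tt.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            key = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
            pkey = tuple(sorted(
                lf.taxon.label for lf in node.parent_node.leaf_iter()))
            if lab[pkey] == "nonrestricted" and lab[key] == "restricted":
                gains.append(set(key))
        if gains and all(g <= rhizobiales for g in gains):
            found = True
            break
    return dict(
        min_changes=tt.min_changes,
        root_nonrestricted="nonrestricted" in root_state_set(tt),
        nonrestricted_root_with_rhizobiales_gains=found,
        n_leaves=len(tt.leaf_labels()),
    )


def registration_recovery(seed: int, n_landmarks: int = 20,
                          jitter_sd: float = 0.1) -> dict:
    """Recover a known affine warp from landmark pairs."""
    rng = np.random.default_rng(seed)
    A = np.array([[1.015, 0.02, 3.1], [-0.012, 0.99, -2.4]])
    pts = rng.uniform(50, 1950, (n_landmarks, 2))
    B = np.stack([pts[:, 0], pts[:, 1], np.ones(n_landmarks)], axis=1)
    warped = B @ A.T + rng.normal(0, jitter_sd, (n_landmarks, 2))
    dmap = estimate_distortion(np.hstack([warped, pts]), model="affine")
    corrected = dmap.transform(warped)
    misalign = float(np.sqrt(np.mean(np.sum((corrected - pts) ** 2, axis=1))))
    return dict(residual_rms_px=dmap.residual_rms,
                post_correction_misalignment_px=misalign, n=n_landmarks)
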