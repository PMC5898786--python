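"""End-to-end analysis workflow.

Orchestrates the full chain — quasi-rigid domain decomposition, per-domain
spectral state clustering, state features (interhelical angles, secondary
structure, solvent exposure), kinetics, and binding-mode classification —
from a single configuration mapping, with every random choice funneled
through recorded seeds so reruns are byte-identical.

``make_demo`` emits a complete synthetic study (planted states, water
shell, toy complexes in two planted binding classes) plus the config to
analyze it; ``run_pipeline`` consumes such a config and writes the
standard output bundle (domains.json, states.json, angles.csv,
ss_freq.csv, exposure.csv, kinetics.csv, scores.csv, classes.json).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    binding_analysis,
    kinetics as kinetics_mod,
    rigid_domains,
    state_clustering,
    state_features,
    structure_io,
    synthetic_data,
)
from .state_features import HelixDefinition

__all__ = ["make_demo", "run_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _read_helix_table(path: str | Path) -> list[HelixDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        HelixDefinition(str(r["id"]), str(r["chain"]), int(r["first"]), int(r["last"]))
        for _, r in df.iterrows()
    ]


def _write_helix_table(helices, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "id": h.id,
                "chain": h.chain,
                "first": h.first_residue,
                "last": h.last_residue,
            }
            for h in helices
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# demo study


def make_demo(seed: int, outdir: str | Path, n_frames: int = 300) -> dict:
    """Write a complete synthetic study and the config that analyzes it.

    Four planted states (25° steps of two helix-pair angles per lobe), a
    water shell whose per-state burial exposes one lobe-1 helix per
    state, and six toy complexes in two planted binding classes
    (contacting the exposed sets of states 0 and 1 respectively).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_states = 4
    helix_len = 10
    base_exposure = 0.15
    burial = {}
    for s in range(n_states):
        mask = np.full(88, base_exposure)
        mask[s * helix_len : (s + 1) * helix_len] = 1.0
        burial[s] = mask
    config = synthetic_data.SyntheticConfig(
        planted_states=synthetic_data.default_state_plan(n_states),
        n_frames=n_frames,
        seed=seed,
        water_shell=synthetic_data.WaterShellConfig(burial_mask=burial),
    )
    ensemble, truth = synthetic_data.generate_ensemble(config)
    solvated = synthetic_data.generate_water_shell(
        ensemble, config, frame_state=truth.frame_state, ground_truth=truth
    )
    solvated.frame_interval = 20.0  # ps between frames
    structure_io.write_pdb(solvated, outdir / "ensemble.pdb")
    _write_helix_table(truth.helices, outdir / "helices.tsv")

    # two planted binding classes: contacts on the exposed sets of states 0
    # and 1 (helices A and B), restricted to sterically accessible residues
    # of a clean reference geometry
    ref_cfg = dataclasses.replace(
        config, n_frames=1, coord_noise_sd=0.0, lobe_wobble_deg=0.0,
        planted_states=[config.planted_states[0]],
        state_weights=None, transition_matrix=None,
    )
    ref_frame, _ = synthetic_data.generate_ensemble(ref_cfg)
    ref_frame = ref_frame.frame(0)
    contact_sets = {}
    for cls, window in ((0, range(1, helix_len + 1)), (1, range(helix_len + 1, 2 * helix_len + 1))):
        feasible = synthetic_data.feasible_contact_residues(
            ref_frame, list(window), seed=seed
        )
        if len(feasible) < 3:
            raise RuntimeError(
                f"demo: fewer than 3 accessible contact residues in helix {cls}"
            )
        contact_sets[cls] = feasible[:3]
    complex_dir = outdir / "complexes"
    complex_dir.mkdir(exist_ok=True)
    complexes = []
    subsets = ((0, 1, 2), (0, 1), (1, 2))  # distinct members per class
    for i in range(6):
        cls = i % 2
        contacts = [contact_sets[cls][j] for j in subsets[i // 2]]
        comp = synthetic_data.generate_complex(
            ref_frame, contacts, n_models=3, contact_fraction=1.0, seed=seed + 100 + i
        )
        name = f"complex_{i}.pdb"
        structure_io.write_pdb(comp, complex_dir / name)
        truth.complex_contacts[name] = list(contacts)
        complexes.append(
            {"path": f"complexes/{name}", "cam_chain": "A", "target_chain": "B"}
        )

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "frame_state": truth.frame_state.tolist(),
                "residue_domain": truth.residue_domain.tolist(),
                "state_angles": truth.state_angles,
                "water_counts": truth.water_counts.tolist(),
                "complex_contacts": truth.complex_contacts,
                "planted_classes": [i % 2 for i in range(6)],
            },
            fh,
            indent=1,
            sort_keys=True,
        )

    pipeline_config = {
        "trajectory": "ensemble.pdb",
        "frame_interval_ps": 20.0,
        "helix_table": "helices.tsv",
        "clustering": {
            "k": None,
            "k_range": [2, 8],
            "seed": seed,
            "pair_stride": 1,
            "atoms": "CA",
        },
        "domains": {"k": None, "k_range": [2, 6], "seed": seed},
        "exposure_cutoff": 4.5,
        "contact_cutoff": 4.5,
        "contact_fraction": 0.7,
        "complexes": complexes,
        "binding": {"k": 2},  # two planted binding classes
        "output_dir": "results",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_config, fh, sort_keys=True)
    return pipeline_config


# ---------------------------------------------------------------------------
# pipeline


def _domain_atom_selection(topology, residue_domain, domain, atom_mode="heavy"):
    """Atom indices of the residues assigned to one domain.

    ``atom_mode="heavy"`` keeps all heavy atoms; ``"CA"`` keeps alpha
    carbons only (coarser, more robust to uncorrelated per-atom noise).
    """
    res_mask = residue_domain == domain
    atom_res = topology.atom_residue_indices
    protein = ~topology.is_water
    mask = protein & res_mask[atom_res]
    if atom_mode == "heavy":
        mask &= topology.is_heavy
    elif atom_mode == "CA":
        mask &= topology.names.astype(str) == "CA"
    else:
        raise ValueError(f"unknown atom_mode: {atom_mode!r}")
    return np.flatnonzero(mask)


def run_pipeline(config: dict, base_dir: str | Path = ".") -> dict:
    """Execute all stages on one trajectory; write the output bundle.

    Returns a dict of in-memory results keyed by stage. Any stage failure
    raises with the stage name prepended.
    """
    base = Path(base_dir)
    outdir = base / config.get("output_dir", "results")
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    results: dict = {"config_hash": chash}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # --- input
    ensemble = stage("load")(structure_io.read_pdb, base / config["trajectory"])
    ensemble.frame_interval = config.get("frame_interval_ps")
    helices = stage("load")(_read_helix_table, base / config["helix_table"])

    # --- quasi-rigid domains
    dom_cfg = config.get("domains", {})
    protein = ensemble.subset_frames(range(ensemble.n_frames))
    fluct = stage("rigid_domains")(rigid_domains.fluctuation_matrix, protein)
    partition = stage("rigid_domains")(
        rigid_domains.decompose,
        fluct,
        k=dom_cfg.get("k"),
        k_range=tuple(dom_cfg.get("k_range", (2, 6))),
        seed=dom_cfg.get("seed", 0),
    )
    results["domains"] = partition
    with open(outdir / "domains.json", "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "n_domains": int(partition.n_domains),
                "residue_domain": {
                    str(key[1]): int(d)
                    for key, d in zip(fluct.residue_index, partition.residue_domain)
                },
                "eigenvalues": [float(v) for v in partition.eigenvalues[:12]],
            },
            fh,
            indent=1,
            sort_keys=True,
        )

    # --- per-domain state clustering
    cl_cfg = config.get("clustering", {})
    seed = cl_cfg.get("seed", 0)
    states_out = {}
    domain_states: dict[int, state_clustering.StateAssignment] = {}
    # map the protein-residue partition onto the full residue list
    # (waters and any unpartitioned residues get -1: never selected)
    key_to_index = {key: i for i, key in enumerate(ensemble.topology.residues)}
    full_domain = np.full(ensemble.topology.n_residues, -1, dtype=int)
    for key, d in zip(fluct.residue_index, partition.residue_domain):
        full_domain[key_to_index[key]] = d
    for d in range(partition.n_domains):
        sel = _domain_atom_selection(
            ensemble.topology,
            full_domain,
            d,
            atom_mode=cl_cfg.get("atoms", "heavy"),
        )
        assignment, model = stage("state_clustering")(
            state_clustering.assign_states,
            ensemble,
            sel,
            k=cl_cfg.get("k"),
            k_range=tuple(cl_cfg.get("k_range", (2, 10))),
            pair_stride=cl_cfg.get("pair_stride", 1),
            seed=seed,
        )
        domain_states[d] = assignment
        states_out[f"domain_{d}"] = {
            "k": int(model.k),
            "sigma": float(model.sigma),
            "labels": [int(x) for x in assignment.labels],
            "representatives": [int(x) for x in assignment.representative_frame],
            "state_sizes": [int(x) for x in assignment.state_sizes],
            "eigenvalues": [float(v) for v in model.eigenvalues[:12]],
            "seed": seed,
        }
    with open(outdir / "states.json", "w") as fh:
        json.dump({"config_hash": chash, **states_out}, fh, indent=1, sort_keys=True)

    # --- interhelical angles, tagged with per-domain state labels
    angle_rows = []
    angles = stage("features")(
        state_features.interhelical_angles, ensemble, helices, "within_lobe"
    )
    for d, assignment in domain_states.items():
        labels = assignment.labels
        tagged = angles.copy()
        tagged["domain"] = d
        tagged["state"] = labels[tagged["frame"].to_numpy()]
        angle_rows.append(tagged)
    angles_df = pd.concat(angle_rows, ignore_index=True)
    angles_df.to_csv(outdir / "angles.csv", index=False)
    results["angles"] = angles_df

    # --- secondary structure frequencies per domain state
    ss_rows = []
    for d, assignment in domain_states.items():
        for s in range(assignment.n_states):
            frames = np.flatnonzero(assignment.labels == s)
            freq = stage("features")(
                state_features.secondary_structure_frequency, ensemble, frames
            )
            freq = freq.reset_index()
            freq.insert(0, "domain", d)
            freq.insert(1, "state", s)
            ss_rows.append(freq)
    ss_df = pd.concat(ss_rows, ignore_index=True)
    ss_df.to_csv(outdir / "ss_freq.csv", index=False)
    results["ss_freq"] = ss_df

    # --- solvent exposure and relative exposure per domain state
    exposure_rows = []
    rel_by_domain = {}
    has_water = bool(np.any(ensemble.topology.is_water))
    if has_water:
        cutoff = config.get("exposure_cutoff", 4.5)
        for d, assignment in domain_states.items():
            prof = stage("exposure")(
                state_features.solvent_exposure,
                ensemble,
                cutoff,
                None,
                assignment.labels,
            )
            rel = state_features.relative_exposure(prof)
            rel_by_domain[d] = rel
            tidy = prof.reset_index(names="state").melt(
                id_vars="state", var_name="residue", value_name="exposure"
            )
            tidy_rel = rel.reset_index(names="state").melt(
                id_vars="state", var_name="residue", value_name="relative_exposure"
            )
            tidy = tidy.merge(tidy_rel, on=["state", "residue"])
            tidy.insert(0, "domain", d)
            exposure_rows.append(tidy)
        exp_df = pd.concat(exposure_rows, ignore_index=True)
        exp_df.to_csv(outdir / "exposure.csv", index=False)
        results["exposure"] = exp_df

    # --- kinetics per domain
    kin_rows = []
    if ensemble.frame_interval:
        for d, assignment in domain_states.items():
            kin = stage("kinetics")(
                kinetics_mod.transition_kinetics,
                assignment.labels,
                ensemble.frame_interval,
            )
            for ai, a in enumerate(kin.states):
                for bi, b in enumerate(kin.states):
                    if ai == bi:
                        continue
                    kin_rows.append(
                        {
                            "domain": d,
                            "from_state": int(a),
                            "to_state": int(b),
                            "mean_time_ps": kin.mean_time[ai, bi],
                            "rate_per_ps": kin.rate[ai, bi],
                            "n_events": int(kin.n_events[ai, bi]),
                            "n_censored": int(kin.n_censored[ai, bi]),
                        }
                    )
        kin_df = pd.DataFrame(kin_rows)
        kin_df.to_csv(outdir / "kinetics.csv", index=False)
        results["kinetics"] = kin_df

    # --- binding analysis per domain
    complexes = config.get("complexes", [])
    if complexes and rel_by_domain:
        score_rows = []
        classes_out = {}
        for d, rel in rel_by_domain.items():
            dists, tfracs, ids = [], [], []
            for entry in complexes:
                cid = Path(entry["path"]).stem
                comp = stage("binding")(
                    structure_io.read_pdb, base / entry["path"]
                )
                cv = stage("binding")(
                    binding_analysis.contact_vector,
                    comp,
                    entry["cam_chain"],
                    entry["target_chain"],
                    config.get("contact_cutoff", 4.5),
                    config.get("contact_fraction", 0.7),
                    entry.get("residue_map"),
                    cid,
                )
                md_ = stage("binding")(binding_analysis.matching_scores, rel, cv)
                tfracs.append(binding_analysis.contact_residue_types(cv))
                dists.append(md_)
                ids.append(cid)
                for si, st in enumerate(md_.states):
                    score_rows.append(
                        {
                            "domain": d,
                            "complex": cid,
                            "state": int(st),
                            "raw": float(md_.raw[si]),
                            "normalized": float(md_.normalized[si]),
                        }
                    )
            cls = stage("binding")(
                binding_analysis.classify_binding_modes,
                dists,
                config.get("binding", {}).get("k"),
                seed,
                (2, min(6, len(dists) - 1)),
                tfracs,
            )
            classes_out[f"domain_{d}"] = {
                "labels": {i: int(c) for i, c in zip(ids, cls.labels)},
                "k": int(cls.k),
                "class_mean": [[float(v) for v in row] for row in cls.class_mean],
                "class_std": [[float(v) for v in row] for row in cls.class_std],
                "type_mean": [[float(v) for v in row] for row in cls.type_mean],
                "type_std": [[float(v) for v in row] for row in cls.type_std],
            }
        pd.DataFrame(score_rows).to_csv(outdir / "scores.csv", index=False)
        with open(outdir / "classes.json", "w") as fh:
            json.dump(
                {"config_hash": chash, **classes_out}, fh, indent=1, sort_keys=True
            )
        results["classes"] = classes_out
    return results
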