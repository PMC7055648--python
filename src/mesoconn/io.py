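"""On-disk formats: HDF5 for studies and networks, CSV/JSON for partitions.

Schemas
-------
Study (one HDF5 file per subject): datasets ``positions`` (n x 3 float),
``hemisphere`` (n bytes), group ``recordings/<condition>`` with ``traces``
(n x T float) and attributes ``frame_rate`` and ``condition``; planted
ground truth under group ``truth``.

FCNetwork (HDF5): datasets ``weights`` (N x N float64) and ``coords``
(N x 3), attributes ``condition`` and ``subject_id``; optional CSV edge list
``i,j,weight`` (0-based, upper triangle only).

Parcellation: CSV ``cell_id,subject_id,parcel_id`` plus a JSON sidecar with
centroids, homotopic map, membership, params and seed; the round trip is
lossless.

Partitions: CSV ``node_id,module_id`` (0-based nodes, 1-based modules);
hierarchies as JSON; flexibility as CSV ``node_id,flexibility``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .community import Hierarchy, Partition
from .connectivity import FCNetwork
from .errors import SchemaError
from .parcellation import Parcellation, ParcellationParams
from .synthetic import (
    CellPopulation,
    FluorescenceRecording,
    PlantedStructure,
    StudyDataset,
)


def _require(group, kind: str, name: str):
    container = group.attrs if kind == "attribute" else group
    if name not in container:
        raise SchemaError(f"missing {kind} {name!r} in {group.name or '/'}")
    return container[name]


# ---------------------------------------------------------------------------
# study datasets


def save_study(dataset: StudyDataset, out_dir: str | Path, config_hash: str = "") -> list[Path]:
    """One HDF5 file per subject; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    s = dataset.structure
    for subject in dataset.subjects:
        pop = dataset.populations[subject]
        path = out_dir / f"{subject}.h5"
        with h5py.File(path, "w") as f:
            f.attrs["subject_id"] = subject
            f.attrs["midline_axis"] = pop.midline_axis
            if config_hash:
                f.attrs["config_hash"] = config_hash
            f.create_dataset("positions", data=pop.positions)
            f.create_dataset(
                "hemisphere", data=np.char.encode(pop.hemisphere.astype(str))
            )
            rec_grp = f.create_group("recordings")
            for (subj, cond), rec in dataset.recordings.items():
                if subj != subject:
                    continue
                g = rec_grp.create_group(cond)
                g.create_dataset("traces", data=rec.traces)
                g.attrs["frame_rate"] = rec.frame_rate
                g.attrs["condition"] = cond
            t = f.create_group("truth")
            if s.fine_of_cell is not None:
                t.create_dataset("fine_of_cell", data=s.fine_of_cell)
                t.create_dataset("coarse_of_fine", data=s.coarse_of_fine)
            t.create_dataset("flexible_cells", data=s.flexible_cells)
            t.attrs["within_fine_corr"] = s.within_fine_corr
            t.attrs["within_coarse_corr"] = s.within_coarse_corr
            t.attrs["between_corr"] = s.between_corr
            t.attrs["decay_rate"] = s.decay_rate
            t.attrs["global_amp"] = s.global_amp
            t.attrs["noise_sd"] = s.noise_sd
            remap = t.create_group("condition_remap")
            for cond, lab in s.condition_remap.items():
                remap.create_dataset(cond, data=lab)
        paths.append(path)
    return paths


def load_study(data_dir: str | Path) -> StudyDataset:
    """Load every ``*.h5`` subject file in a directory."""
    files = sorted(Path(data_dir).glob("*.h5"))
    if not files:
        raise SchemaError(f"no subject files in {data_dir}")
    populations: dict[str, CellPopulation] = {}
    recordings: dict[tuple[str, str], FluorescenceRecording] = {}
    structure: PlantedStructure | None = None
    for path in files:
        with h5py.File(path, "r") as f:
            subject = str(_require(f, "attribute", "subject_id"))
            positions = np.asarray(_require(f, "dataset", "positions"))
            hemisphere = np.char.decode(
                np.asarray(_require(f, "dataset", "hemisphere"))
            )
            populations[subject] = CellPopulation(
                positions=positions,
                hemisphere=hemisphere,
                subject_id=subject,
                midline_axis=int(f.attrs.get("midline_axis", 0)),
            )
            recs = _require(f, "group", "recordings")
            for cond in recs:
                g = recs[cond]
                recordings[(subject, cond)] = FluorescenceRecording(
                    traces=np.asarray(_require(g, "dataset", "traces")),
                    frame_rate=float(_require(g, "attribute", "frame_rate")),
                    condition=str(_require(g, "attribute", "condition")),
                    subject_id=subject,
                )
            if structure is None and "truth" in f:
                t = f["truth"]
                fine = (
                    np.asarray(t["fine_of_cell"], dtype=np.intp)
                    if "fine_of_cell" in t
                    else None
                )
                coarse = (
                    np.asarray(t["coarse_of_fine"], dtype=np.intp)
                    if "coarse_of_fine" in t
                    else None
                )
                structure = PlantedStructure(
                    fine_of_cell=fine,
                    coarse_of_fine=coarse,
                    within_fine_corr=float(t.attrs["within_fine_corr"]),
                    within_coarse_corr=float(t.attrs["within_coarse_corr"]),
                    between_corr=float(t.attrs["between_corr"]),
                    decay_rate=float(t.attrs["decay_rate"]),
                    global_amp=float(t.attrs["global_amp"]),
                    noise_sd=float(t.attrs["noise_sd"]),
                    flexible_cells=np.asarray(t["flexible_cells"], dtype=np.intp),
                    condition_remap={
                        c: np.asarray(t["condition_remap"][c], dtype=np.intp)
                        for c in t["condition_remap"]
                    },
                )
    if structure is None:
        structure = PlantedStructure(fine_of_cell=None, coarse_of_fine=None)
    return StudyDataset(populations=populations, recordings=recordings, structure=structure)


def load_recording(path: str | Path, condition: str) -> FluorescenceRecording:
    """Load a single recording from a subject file, validating the schema."""
    with h5py.File(path, "r") as f:
        subject = str(_require(f, "attribute", "subject_id"))
        recs = _require(f, "group", "recordings")
        if condition not in recs:
            raise SchemaError(f"missing group recordings/{condition}")
        g = recs[condition]
        return FluorescenceRecording(
            traces=np.asarray(_require(g, "dataset", "traces")),
            frame_rate=float(_require(g, "attribute", "frame_rate")),
            condition=str(_require(g, "attribute", "condition")),
            subject_id=subject,
        )


# ---------------------------------------------------------------------------
# networks


def save_network(net: FCNetwork, path: str | Path, config_hash: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=net.weights.astype(np.float64))
        f.create_dataset("coords", data=net.coords)
        f.attrs["condition"] = net.condition
        f.attrs["subject_id"] = net.subject_id
        if config_hash:
            f.attrs["config_hash"] = config_hash
    return path


def load_network(path: str | Path, expected_hash: str = "") -> FCNetwork:
    with h5py.File(path, "r") as f:
        if expected_hash:
            found = str(f.attrs.get("config_hash", ""))
            if found != expected_hash:
                raise SchemaError(
                    f"config hash mismatch: file has {found!r}, expected {expected_hash!r}"
                )
        return FCNetwork(
            weights=np.asarray(_require(f, "dataset", "weights")),
            coords=np.asarray(_require(f, "dataset", "coords")),
            condition=str(_require(f, "attribute", "condition")),
            subject_id=str(_require(f, "attribute", "subject_id")),
        )


def save_network_edgelist(net: FCNetwork, path: str | Path) -> Path:
    """CSV edge list ``i,j,weight`` (0-based, upper triangle only)."""
    iu = np.triu_indices(net.n_nodes, k=1)
    df = pd.DataFrame({"i": iu[0], "j": iu[1], "weight": net.weights[iu]})
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_network_edgelist(path: str | Path, n_nodes: int) -> NDArrayFloat:
    df = pd.read_csv(path)
    for col in ("i", "j", "weight"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    w = np.zeros((n_nodes, n_nodes))
    w[df["i"], df["j"]] = df["weight"]
    return w + w.T


NDArrayFloat = np.ndarray


# ---------------------------------------------------------------------------
# parcellations and partitions


def save_parcellation(parc: Parcellation, csv_path: str | Path) -> tuple[Path, Path]:
    """CSV of cell assignments plus a JSON sidecar; lossless round trip."""
    csv_path = Path(csv_path)
    rows = []
    for subject, assign in parc.parcel_of_cell.items():
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(len(assign)),
                    "subject_id": subject,
                    "parcel_id": assign,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "n_parcels": int(parc.n_parcels),
        "parcel_centroids": parc.parcel_centroids.tolist(),
        "homotopic_partner": parc.homotopic_partner.tolist(),
        "functional_of_parcel": parc.functional_of_parcel.tolist(),
        "members": [m.tolist() for m in parc.members],
        "spatial_centroids": parc.spatial_centroids.tolist(),
        "hemisphere_of_parcel": parc.hemisphere_of_parcel.tolist(),
        "params": None
        if parc.params is None
        else {
            "k_spatial": parc.params.k_spatial,
            "k_functional": parc.params.k_functional,
            "n_replicates": parc.params.n_replicates,
            "max_diameter": parc.params.max_diameter,
            "min_gap": parc.params.min_gap,
            "seed": parc.params.seed,
        },
        "stats": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in parc.stats.items()
        },
    }
    sidecar.write_text(json.dumps(meta))
    return csv_path, sidecar


def load_parcellation(csv_path: str | Path) -> Parcellation:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("cell_id", "subject_id", "parcel_id"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {csv_path}")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    parcel_of_cell = {
        str(subject): grp.sort_values("cell_id")["parcel_id"].to_numpy(dtype=np.intp)
        for subject, grp in df.groupby("subject_id")
    }
    params = meta["params"]
    return Parcellation(
        parcel_of_cell=parcel_of_cell,
        parcel_centroids=np.asarray(meta["parcel_centroids"], dtype=float),
        homotopic_partner=np.asarray(meta["homotopic_partner"], dtype=np.intp),
        n_parcels=int(meta["n_parcels"]),
        functional_of_parcel=np.asarray(meta["functional_of_parcel"], dtype=np.intp),
        members=[np.asarray(m, dtype=np.intp) for m in meta["members"]],
        spatial_centroids=np.asarray(meta["spatial_centroids"], dtype=float),
        hemisphere_of_parcel=np.asarray(meta["hemisphere_of_parcel"], dtype=str),
        params=None if params is None else ParcellationParams(**params),
        stats=meta.get("stats", {}),
    )


def save_partition(partition: Partition, path: str | Path) -> Path:
    """CSV ``node_id,module_id`` with 0-based nodes and 1-based modules."""
    df = pd.DataFrame(
        {
            "node_id": np.arange(partition.n_nodes),
            "module_id": partition.labels + 1,
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path)
    for col in ("node_id", "module_id"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    labels = df.sort_values("node_id")["module_id"].to_numpy(dtype=np.intp) - 1
    return Partition(labels=labels)


def save_hierarchy(hier: Hierarchy, path: str | Path) -> Path:
    payload = {
        "levels": [lev.labels.tolist() for lev in hier.levels],
        "q_values": list(hier.q_values),
        "gamma_provenance": list(hier.gamma_provenance),
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_hierarchy(path: str | Path) -> Hierarchy:
    payload = json.loads(Path(path).read_text())
    return Hierarchy(
        levels=[Partition(labels=np.asarray(l, dtype=np.intp)) for l in payload["levels"]],
        q_values=payload.get("q_values", []),
        gamma_provenance=payload.get("gamma_provenance", []),
    )


def save_flexibility(f: np.ndarray, path: str | Path) -> Path:
    df = pd.DataFrame({"node_id": np.arange(len(f)), "flexibility": f})
    path = Path(path)
    df.to_csv(path, index=False)
    return path
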