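"""Persistence for posterior fits: self-describing columnar draws + metadata.

Parameter draws are written as a long CSV (``parameter, index, chain, draw,
value``) so any downstream tool can consume them; the per-individual
pointwise log-likelihood (large, numeric-only) is stored as a compressed
``.npz`` next to it, and a JSON sidecar records the model spec, species
order, calendar and sampler configuration needed to reconstruct the
:class:`~cjsclim.inference.PosteriorDraws` object exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .capture import OccasionCalendar
from .climate import ClimateSeries
from .inference import PosteriorDraws
from .likelihood import ModelSpec

__all__ = ["save_fit", "load_fit"]


def save_fit(fit: PosteriorDraws, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in fit.params.items():
        if name.startswith("_"):
            continue
        C, D = arr.shape[:2]
        flat = arr.reshape(C, D, -1)
        for k in range(flat.shape[2]):
            for c in range(C):
                for d in range(D):
                    rows.append((name, k, c, d, flat[c, d, k]))
    draws_path = out / "draws.csv"
    pd.DataFrame(
        rows, columns=["parameter", "index", "chain", "draw", "value"]
    ).to_csv(draws_path, index=False)
    point_path = out / "pointwise.npz"
    np.savez_compressed(
        point_path,
        pointwise=fit.pointwise,
        individuals=fit.individuals.astype(str),
        species_of_individual=fit.species_of_individual.astype(str),
        p_occ=fit.params["_p_occ"],
    )
    meta = {
        "spec": {
            "phi_structure": fit.spec.phi_structure,
            "p_structure": fit.spec.p_structure,
            "covariate_alignment": fit.spec.covariate_alignment,
        },
        "species": list(map(str, fit.species)),
        "param_shapes": {
            name: list(arr.shape)
            for name, arr in fit.params.items()
            if not name.startswith("_")
        },
        "calendar": {
            "occasion_years": fit.calendar.occasion_years.tolist(),
            "sampled": fit.calendar.sampled.astype(int).tolist(),
        },
        "seed": fit.seed,
        "config": fit.config,
    }
    meta_path = out / "fit.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"draws": draws_path, "pointwise": point_path, "meta": meta_path}


def load_fit(fit_dir, climate: ClimateSeries | None = None) -> PosteriorDraws:
    out = Path(fit_dir)
    meta = json.loads((out / "fit.json").read_text())
    spec = ModelSpec(**meta["spec"])
    calendar = OccasionCalendar(
        np.array(meta["calendar"]["occasion_years"]),
        np.array(meta["calendar"]["sampled"], dtype=bool),
    )
    df = pd.read_csv(out / "draws.csv")
    params: dict[str, np.ndarray] = {}
    for name, shape in meta["param_shapes"].items():
        sub = df[df["parameter"] == name]
        C, D = shape[0], shape[1]
        k_size = int(np.prod(shape[2:])) if len(shape) > 2 else 1
        flat = np.empty((C, D, k_size))
        flat[
            sub["chain"].to_numpy(), sub["draw"].to_numpy(), sub["index"].to_numpy()
        ] = sub["value"].to_numpy()
        params[name] = flat.reshape(shape)
    npz = np.load(out / "pointwise.npz", allow_pickle=False)
    params["_p_occ"] = npz["p_occ"]
    return PosteriorDraws(
        spec=spec,
        species=meta["species"],
        params=params,
        pointwise=npz["pointwise"],
        individuals=npz["individuals"],
        species_of_individual=npz["species_of_individual"],
        calendar=calendar,
        climate=climate,
        seed=meta["seed"],
        config=meta["config"],
    )
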