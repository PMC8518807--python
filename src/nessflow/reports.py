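"""Deterministic CSV/JSON report writing.

All numeric output is emitted at full double precision (17 significant
digits) with canonical column order and sorted JSON keys, so re-running a
configuration byte-reproduces every artifact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    return obj


def write_report(results, fmt: str, path) -> Path:
    """Write ``results`` as CSV (DataFrame / dict of columns) or JSON.

    CSV: canonical column order as given, 17 significant digits, UTF-8,
    newline-terminated.  JSON: keys sorted.  An empty result set yields a
    header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            results.to_csv(fh, index=False, float_format="%.17g",
                           lineterminator="\n")
        return path
    if fmt == "json":
        text = json.dumps(_jsonify(results), sort_keys=True, indent=1)
        path.write_text(text + "\n", encoding="utf-8")
        return path
    raise ValueError(f"unknown report format {fmt!r}")


def trajectory_frame(network, trajectory) -> pd.DataFrame:
    """Trajectory as a tidy frame: t then one column per species."""
    data = {"t": trajectory.times}
    for i, name in enumerate(network.species_names):
        data[f"c_{name}"] = trajectory.states[:, i]
    return pd.DataFrame(data)


def thermo_series_frame(network, trajectory) -> pd.DataFrame:
    """Time series of rates, affinities, entropy components and the GEC
    split: columns t, c_*, v_*, Af_*, sigma_int, sigma_exch, dFP, dJP, dP."""
    from .network import pair_rates
    from .thermo import (
        entropy_exchange,
        gec_point,
        reference_equilibrium,
    )

    ref = None
    if not network.is_closed:
        ref = reference_equilibrium(network, trajectory.states[0])
    rows = []
    for t, c, dc in zip(trajectory.times, trajectory.states,
                        trajectory.derivatives):
        row = {"t": t}
        for i, name in enumerate(network.species_names):
            row[f"c_{name}"] = c[i]
        vf, vr = pair_rates(network, c)
        RT = network.gas_constant * network.temperature
        for pid, f, r in zip(network.pair_ids, vf, vr):
            row[f"v_{pid}"] = f - r
            row[f"Af_{pid}"] = RT * np.log(f / r)
        _, dP, dFP, dJP, s_int = gec_point(network, c, dc)
        row["sigma_int"] = s_int
        row["sigma_exch"] = (0.0 if network.is_closed
                             else entropy_exchange(network, c, ref=ref))
        row["dFP"] = dFP
        row["dJP"] = dJP
        row["dP"] = dP
        rows.append(row)
    return pd.DataFrame(rows)


def steady_state_record(network, state) -> dict:
    return {
        "conc": {n: c for n, c in zip(network.species_names, state.conc)},
        "residual_norm": state.residual_norm,
        "verdict": state.verdict,
        "n_unstable": state.n_unstable,
        "eigenvalues": [{"re": z.real, "im": z.imag}
                        for z in np.atleast_1d(state.jacobian_eigenvalues)],
    }
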