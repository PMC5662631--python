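import numpy as np
import pytest

from cbgt import cells, msn


@pytest.fixture(scope="session")
def intact_morph():
    return msn.build_morphology("D1", seed=0)


@pytest.fixture(scope="session")
def zero_bias_params():
    """Cell parameters with all bias currents at zero (isolated rest)."""
    return {
        "th": cells.THParams(i_app=0.0),
        "stn": cells.STNParams(i_app=0.0),
        "gpe": cells.GPParams(i_app=0.0),
        "gpi": cells.GPParams(i_app=0.0),
        "py": cells.PYParams(i_app=0.0),
        "da": cells.DAParams(i_app=0.0),
    }


def integrate_rhs(rhs_vec, y0, t_end, dt_out=0.05, rtol=1e-8, atol=1e-10):
    """Reference adaptive integration (LSODA) of a packed rhs."""
    from scipy.integrate import solve_ivp
    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    sol = solve_ivp(rhs_vec, (0.0, t_end), y0, t_eval=t_eval,
                    method="LSODA", rtol=rtol, atol=atol, max_step=1.0)
    assert sol.success
    return sol.t, sol.y


def pack_cell(cell_type, params, i_ext=0.0, v0=None):
    """(rhs_vec, y0, gate names) for solve_ivp reference integrations."""
    if cell_type == "th":
        names = cells.TH_GATES
        v0 = -66.0 if v0 is None else v0
        s0 = cells.th_steady_state(v0, params)

        def f(t, y):
            s = cells.CellState(y[0], dict(zip(names, y[1:])))
            i = i_ext(t) if callable(i_ext) else i_ext
            d = cells.th_rhs(s, -i, params)  # i_ext enters as -i_syn
            return [d.v] + [d.gates[k] for k in names]
        y0 = [s0.v] + [s0.gates[k] for k in names]
        return f, y0, names
    if cell_type == "stn":
        names = cells.STN_GATES
        v0 = -62.0 if v0 is None else v0
        s0 = cells.stn_steady_state(v0, params)

        def f(t, y):
            s = cells.CellState(y[0], dict(zip(names, y[1:-1])),
                                max(y[-1], 0.0))
            i = i_ext(t) if callable(i_ext) else i_ext
            d = cells.stn_rhs(s, -i, params)
            return [d.v] + [d.gates[k] for k in names] + [d.ca]
        y0 = [s0.v] + [s0.gates[k] for k in names] + [s0.ca]
        return f, y0, names
    if cell_type in ("gpe", "gpi"):
        names = cells.GP_GATES
        v0 = -65.0 if v0 is None else v0
        s0 = cells.gp_steady_state(v0, params)
        rhs = cells.gpe_rhs if cell_type == "gpe" else cells.gpi_rhs

        def f(t, y):
            s = cells.CellState(y[0], dict(zip(names, y[1:-1])),
                                max(y[-1], 0.0))
            i = i_ext(t) if callable(i_ext) else i_ext
            d = rhs(s, {"stn": -i}, params)
            return [d.v] + [d.gates[k] for k in names] + [d.ca]
        y0 = [s0.v] + [s0.gates[k] for k in names] + [s0.ca]
        return f, y0, names
    if cell_type == "py":
        names = cells.PY_GATES
        v0 = -70.3 if v0 is None else v0
        s0 = cells.py_steady_state(v0, params)

        def f(t, y):
            s = cells.CellState(y[0], dict(zip(names, y[1:])))
            i = i_ext(t) if callable(i_ext) else i_ext
            d = cells.py_rhs(s, 0.0, i, params)
            return [d.v] + [d.gates[k] for k in names]
        y0 = [s0.v] + [s0.gates[k] for k in names]
        return f, y0, names
    if cell_type == "da":
        names = cells.DA_GATES
        v0 = -60.0 if v0 is None else v0
        s0 = cells.da_steady_state(v0, params)

        def f(t, y):
            s = cells.CellState(y[0], dict(zip(names, y[1:-1])),
                                max(y[-1], 0.0))
            i = i_ext(t) if callable(i_ext) else i_ext
            d = cells.da_rhs(s, i, params)
            return [d.v] + [d.gates[k] for k in names] + [d.ca]
        y0 = [s0.v] + [s0.gates[k] for k in names] + [s0.ca]
        return f, y0, names
    raise ValueError(cell_type)


def count_spikes(t, v, thr=-20.0, refractory=2.0):
    up = np.where((v[1:] >= thr) & (v[:-1] < thr))[0]
    times = t[up + 1]
    keep, last = [], -np.inf
    for tt in times:
        if tt - last >= refractory:
            keep.append(tt)
            last = tt
    return np.asarray(keep)
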