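"""Exact propagation of linear ODE systems with piecewise-constant coefficients.

Every forcing function in this package (body-water label availability and the
label-enrichment systems it drives) is itself the solution of a linear ODE with
piecewise-constant inputs, so the full state (forcing + observables + an affine
'1' component) evolves as z' = M_j z on each protocol phase. Propagating with
matrix exponentials is exact up to floating point and much cheaper than a
general-purpose integrator in an optimizer's inner loop.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


class PiecewiseLinearSystem:
    """z' = M_j z on [b_j, b_{j+1}), with b_0 the initial time.

    Parameters
    ----------
    breakpoints : sequence of float
        Strictly increasing phase-change times; the first entry is the
        initial time, the last phase extends to +inf.
    matrices : sequence of (n, n) arrays
        One system matrix per phase (``len(matrices) == len(breakpoints)``).
    z0 : (n,) array
        State at ``breakpoints[0]``.
    """

    def __init__(self, breakpoints, matrices, z0):
        self.breakpoints = np.asarray(breakpoints, dtype=float)
        if self.breakpoints.ndim != 1 or np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(matrices) != len(self.breakpoints):
            raise ValueError("need one matrix per phase")
        self.matrices = [np.asarray(m, dtype=float) for m in matrices]
        self.z0 = np.asarray(z0, dtype=float)

    def solve(self, times):
        """State at each requested time (times need not be sorted).

        Returns an array of shape ``(len(times), n)``.
        """
        times = np.asarray(times, dtype=float)
        flat = np.atleast_1d(times).ravel()
        if flat.size and flat.min() < self.breakpoints[0] - 1e-12:
            raise ValueError("cannot propagate backwards from the initial time")
        order = np.argsort(flat, kind="stable")
        out = np.empty((flat.size, self.z0.size))

        # collect every propagation segment first so all matrix exponentials
        # can be computed in one stacked call
        segments = []  # (phase, dt) per propagation step
        emit_after = []  # output index to record after each segment (or None)
        t_cur = self.breakpoints[0]
        phase = 0
        n_phase = len(self.breakpoints)
        for idx in order:
            t = max(flat[idx], self.breakpoints[0])
            while phase + 1 < n_phase and t > self.breakpoints[phase + 1]:
                dt = self.breakpoints[phase + 1] - t_cur
                if dt > 0:
                    segments.append((phase, dt))
                    emit_after.append(None)
                t_cur = self.breakpoints[phase + 1]
                phase += 1
            dt = t - t_cur
            if dt > 0:
                segments.append((phase, dt))
                emit_after.append(None)
                t_cur = t
            if emit_after:
                emit_after[-1] = idx if emit_after[-1] is None else emit_after[-1]
            if dt <= 0:
                # no propagation needed (duplicate or initial time)
                segments.append((phase, 0.0))
                emit_after.append(idx)

        if segments:
            stack = np.array([self.matrices[p] * dt for p, dt in segments])
            props = expm(stack)
        z = self.z0.copy()
        for i, (seg, idx) in enumerate(zip(segments, emit_after)):
            if seg[1] > 0:
                z = props[i] @ z
            if idx is not None:
                out[idx] = z
        return out.reshape(times.shape + (self.z0.size,)) if times.ndim else out[0]
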