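"""Numba-compiled inner loops for the lattice swap dynamics.

The sweep kernel is the hot path: one call visits every lattice site once
in a supplied random order, proposes an exchange with a random von Neumann
neighbour, and applies the acceptance rule.  All randomness is drawn
outside the kernel from a seeded numpy Generator so trajectories are
reproducible and the kernel stays pure.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RULE_METROPOLIS = 0
RULE_BINDING = 1

# neighbour offsets: up, down, left, right
_DR = np.array([-1, 1, 0, 0], dtype=np.int64)
_DC = np.array([0, 0, -1, 1], dtype=np.int64)


@njit(cache=True)
def _site_binding(grid, energy, r, c, h, w):
    code = grid[r, c]
    b = energy[code, grid[(r - 1) % h, c]]
    b += energy[code, grid[(r + 1) % h, c]]
    b += energy[code, grid[r, (c - 1) % w]]
    b += energy[code, grid[r, (c + 1) % w]]
    return b


@njit(cache=True)
def sweep(
    grid,
    energy,
    order,
    nbr_choice,
    urand,
    theta,
    b_ref,
    rule,
    count_identical,
    accepted,
):
    """One iteration: every site proposes one exchange, in the given order.

    Parameters
    ----------
    grid : int8 (H, W), modified in place
    energy : float64 (7, 7) pairwise interaction energies
    order : int64 (H*W,) permutation of flat site indices
    nbr_choice : int8 (H*W,) neighbour index 0-3 (up/down/left/right) per site
    urand : float64 (H*W,) uniforms for the acceptance draw
    theta : float, energy scale of the acceptance rule
    b_ref : float, baseline binding subtracted under the binding rule (the
        weakest possible two-site binding, so the least-bound pair moves
        with probability ~1)
    rule : 0 = Metropolis on the binding change,
           1 = p(move) = exp(-(B_cur - b_ref)/theta) (inverse-force law)
    count_identical : whether same-class exchanges mark the accepted mask
    accepted : bool (H, W), modified in place; marks sites that moved
    """
    h, w = grid.shape
    for k in range(order.shape[0]):
        idx = order[k]
        r = idx // w
        c = idx % w
        d = nbr_choice[k]
        r2 = (r + _DR[d]) % h
        c2 = (c + _DC[d]) % w
        ca = grid[r, c]
        cb = grid[r2, c2]
        if rule == RULE_BINDING:
            b_cur = _site_binding(grid, energy, r, c, h, w) + _site_binding(
                grid, energy, r2, c2, h, w
            )
            ok = urand[k] < np.exp(-(b_cur - b_ref) / theta)
            if ok and ca != cb:
                grid[r, c] = cb
                grid[r2, c2] = ca
        else:
            # Metropolis on the binding change of the exchange
            if ca == cb:
                ok = True  # no state change; p = 1
            else:
                b_cur = _site_binding(grid, energy, r, c, h, w) + _site_binding(
                    grid, energy, r2, c2, h, w
                )
                grid[r, c] = cb
                grid[r2, c2] = ca
                b_swap = _site_binding(grid, energy, r, c, h, w) + _site_binding(
                    grid, energy, r2, c2, h, w
                )
                delta = b_swap - b_cur
                if delta >= 0.0:
                    ok = True
                else:
                    ok = urand[k] < np.exp(delta / theta)
                if not ok:
                    grid[r, c] = ca
                    grid[r2, c2] = cb
        if ok and (count_identical or ca != cb):
            accepted[r, c] = True
            accepted[r2, c2] = True
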