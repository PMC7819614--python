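"""Compiled inner loop for circuit-policy assays.

The closed-loop circuit simulation advances every 0.1 s and each fitness
evaluation of the evolutionary search runs one, so this loop is the hot
path of the whole package.  It is written as explicit per-worm loops and
JIT-compiled with numba; all random numbers are pre-drawn from the caller's
numpy Generator, so results are a pure function of the seed and identical
across compiled/interpreted execution.

State conventions match :mod:`thermosteer.plate_simulator`: headings are
absolute lab-frame angles in degrees, ``theta`` is the heading relative to
the warm-pointing vector, and the dorsoventral sign DV is +1 when the
dorsal side faces the cold direction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_TURN_CLASSES = 4
CURVE = 4  # label code for a steering step


@njit(cache=False)
def _hill(T, tthr, kd, n):
    d = T - tthr
    if d <= 0.0:
        return 0.0
    x = d**n
    return x / (kd + x)


@njit(cache=False)
def _wrap(a):
    return 180.0 - (180.0 - a) % 360.0


@njit(cache=False)
def circuit_assay_core(
    n_steps,
    dt,
    rec_stride,
    # worm state
    x, y, alpha, hand,
    # circuit state
    hist, kr, ycirc,
    # circuit parameters
    W, G, gsum, beta, w_cpg, w_nmj, t_osc, tau,
    noise_col, noise_amp, noise_period,
    clamp_nodes, afd_ablated, clamp_y1_flag, clamp_y1_val,
    tthr, kd, hill_n,
    # arena
    Lx, Ly, T_left, T_right, warm_deg, wsign, v_cm,
    # behavior tables (turning disabled when turning_flag is 0)
    turning_flag, turn_probs, exit_cum, disp_cm,
    # open loop (temperature prescribed per step when flag is 1)
    open_flag, T_series,
    # pre-drawn uniforms, one row per step
    u_event, u_exit, u_exitbin, u_sign,
    # outputs (n_rec, n)
    R_x, R_y, R_a, R_dv, R_lab, R_T, R_psi, R_y1, R_neu,
):
    n = x.size
    K = kr.size
    n_theta = turn_probs.shape[1]
    n_phi = exit_cum.shape[4]
    phi_width = 180.0 / n_phi
    deg = np.pi / 180.0

    labels = np.full(n, CURVE, dtype=np.int8)
    y1 = np.zeros(n)
    psi = np.zeros(n)
    s_pre = np.zeros(6)
    y_next = np.zeros(5)

    # record the initial state
    for w in range(n):
        R_x[0, w] = x[w]; R_y[0, w] = y[w]; R_a[0, w] = alpha[w]
        th = _wrap(alpha[w] - warm_deg)
        R_dv[0, w] = 1 if hand[w] * np.sin(th * deg) > 0 else -1
        R_T[0, w] = T_series[0] if open_flag else T_left + (T_right - T_left) * x[w] / Lx
        R_lab[0, w] = CURVE
        R_psi[0, w] = 0.0
        R_y1[0, w] = 0.0
        for j in range(5):
            R_neu[0, w, j] = ycirc[w, j]

    for step in range(n_steps):
        t = step * dt
        tbin = int(t // 600.0)
        if tbin > 2:
            tbin = 2
        y7 = np.sin(2.0 * np.pi * t / t_osc)
        cpg_d = w_cpg / (1.0 + np.exp(-y7))  # CPG drive to DMN
        cpg_v = w_cpg / (1.0 + np.exp(y7))  # anti-phase drive to VMN
        noise_in = 0.0
        if noise_col >= 0:
            noise_in = noise_amp * np.sin(2.0 * np.pi * t / noise_period)

        for w in range(n):
            # -- sense temperature, update the AFD history convolution
            if open_flag:
                T = T_series[step]
            else:
                T = T_left + (T_right - T_left) * x[w] / Lx
            for j in range(K - 1):
                hist[w, j] = hist[w, j + 1]
            hist[w, K - 1] = _hill(T, tthr, kd, hill_n)
            if clamp_y1_flag:
                a1 = clamp_y1_val
            else:
                a1 = 0.0
                for j in range(K):
                    a1 += hist[w, j] * kr[j]
            if afd_ablated:
                a1 = 0.0
            y1[w] = a1

            # -- one Euler step of the five integrated nodes
            s_pre[0] = 1.0 / (1.0 + np.exp(-(a1 + beta[0])))
            for j in range(5):
                s_pre[1 + j] = 1.0 / (1.0 + np.exp(-(ycirc[w, j] + beta[1 + j])))
            for i in range(5):
                drive = 0.0
                for j in range(6):
                    drive += W[i, j] * s_pre[j]
                if i == 3:
                    drive += cpg_d
                elif i == 4:
                    drive += cpg_v
                if i == noise_col:
                    drive += noise_in
                gap = -gsum[i] * ycirc[w, i]
                for k in range(5):
                    gap += G[i, k] * ycirc[w, k]
                ynew = ycirc[w, i] + (dt / tau) * (-ycirc[w, i] + drive + gap)
                if clamp_nodes[i]:
                    ynew = 0.0
                y_next[i] = ynew
            for i in range(5):
                ycirc[w, i] = y_next[i]
            p = w_nmj * (
                1.0 / (1.0 + np.exp(-(ycirc[w, 3] + beta[4])))
                - 1.0 / (1.0 + np.exp(-(ycirc[w, 4] + beta[5])))
            )
            psi[w] = p

            # -- behavioral event
            theta_rel = _wrap(alpha[w] - warm_deg)
            theta_u = abs(theta_rel)
            tb = int(theta_u / 180.0 * n_theta)
            if tb >= n_theta:
                tb = n_theta - 1
            event = CURVE
            region = 0
            if turning_flag:
                frac = int(8.0 * x[w] / Lx)
                if frac > 7:
                    frac = 7
                region = 0 if frac < 2 else (1 if frac < 6 else 2)
                u = u_event[step, w]
                acc = 0.0
                for c in range(N_TURN_CLASSES):
                    acc += turn_probs[c, tb, region, tbin] * dt
                    if u < acc:
                        event = c
                        break
            labels[w] = event

            if event != CURVE:
                # turn: displace by the class mean and redraw the heading
                ue = u_exit[step, w]
                b = n_phi - 1
                for k in range(n_phi):
                    if ue < exit_cum[event, tb, region, tbin, k]:
                        b = k
                        break
                phi_exit = b * phi_width + u_exitbin[step, w] * phi_width
                sgn = 1.0 if u_sign[step, w] < 0.5 else -1.0
                alpha[w] = _wrap(warm_deg + sgn * phi_exit)
                x[w] += wsign * disp_cm[event, 0] * dt
                y[w] += disp_cm[event, 1] * dt
            else:
                # steering: dorsoventral-signed heading change, then advance
                alpha[w] = _wrap(alpha[w] + hand[w] * p * dt)
                x[w] += v_cm * np.cos(alpha[w] * deg) * dt
                y[w] += v_cm * np.sin(alpha[w] * deg) * dt

            if not open_flag:
                for _ in range(2):
                    if x[w] < 0.0:
                        x[w] = -x[w]; alpha[w] = _wrap(180.0 - alpha[w])
                    elif x[w] > Lx:
                        x[w] = 2.0 * Lx - x[w]; alpha[w] = _wrap(180.0 - alpha[w])
                    if y[w] < 0.0:
                        y[w] = -y[w]; alpha[w] = _wrap(-alpha[w])
                    elif y[w] > Ly:
                        y[w] = 2.0 * Ly - y[w]; alpha[w] = _wrap(-alpha[w])

        if (step + 1) % rec_stride == 0:
            slot = (step + 1) // rec_stride
            for w in range(n):
                R_x[slot, w] = x[w]; R_y[slot, w] = y[w]; R_a[slot, w] = alpha[w]
                th = _wrap(alpha[w] - warm_deg)
                R_dv[slot, w] = 1 if hand[w] * np.sin(th * deg) > 0 else -1
                if open_flag:
                    R_T[slot, w] = T_series[step]
                else:
                    R_T[slot, w] = T_left + (T_right - T_left) * x[w] / Lx
                R_lab[slot, w] = labels[w]
                R_psi[slot, w] = psi[w]
                R_y1[slot, w] = y1[w]
                for j in range(5):
                    R_neu[slot, w, j] = ycirc[w, j]
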