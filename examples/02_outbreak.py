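"""Run a single SIR outbreak on a stationary flock and print its course.

A disordered system (Pe, g) = (32, 1) of 900 agents is burned in, 1% of
agents are infected at random, and the coupled spatial + contagion
dynamics runs until no infected agents remain. Theta = beta_b/gamma is
the expected total transmission pressure per infectious period;
T_inf = 1/gamma the mean infectious duration.
"""

import flocksir as fs

mp = fs.ModelParams.from_dimensionless(Pe=32, g=1, N=900)
ep = fs.EpidemicParams.from_theta(Theta=8.0, T_inf=20.0)
print(f"beta_b={ep.beta_b}, gamma={ep.gamma} (Theta={ep.Theta}, T_inf={ep.T_inf})")

streams = fs.spawn_streams(seed=1)
burn = fs.run_burn_in(
    fs.random_particle_state(mp, streams["seeding"]), mp,
    criterion=fs.StationarityCriterion(t_max=1500.0, t_min=400.0),
    rng=streams["spatial"],
)

es = fs.seed_infections(
    fs.EpidemicState.all_susceptible(mp.N), n_seed=round(0.01 * mp.N),
    rng=streams["seeding"],
)
res = fs.run_outbreak(
    burn.state, es, mp, ep,
    rng_spatial=streams["spatial"],
    rng_infection=streams["infection"],
    rng_recovery=streams["recovery"],
)

print(f"outbreak finished: {res.finished}, duration {res.duration:.0f} time units")
print(f"peak infected fraction rho_I = {res.rho_I_peak:.3f}")
print(f"final recovered fraction rho_R(inf) = {res.rho_R_final:.3f}")
print("rho_R(inf) is the outbreak's final size: the fraction of the population")
print("that was infected at some point. The time series (t, n_S, n_I, n_R):")
print(res.time_series.iloc[:: max(1, len(res.time_series) // 10)].to_string(index=False))
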