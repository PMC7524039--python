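# Generates oracle_reference_sva.csv: the same complete 3-site dataset
# harmonized with the independent reference implementation sva::ComBat
# (parametric priors, diagnosis/age/sex protected via mod).
suppressMessages(library(sva))
meas <- read.csv("tests/data/oracle_measurements.csv", row.names = 1)
cov <- read.csv("tests/data/oracle_covariates.csv")
dat <- t(as.matrix(meas))                       # features x samples
mod <- model.matrix(~ dx + age + sex, data = cov)
out <- ComBat(dat = dat, batch = cov$site, mod = mod, par.prior = TRUE)
write.csv(round(t(out), 10), "tests/data/oracle_reference_sva.csv")
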