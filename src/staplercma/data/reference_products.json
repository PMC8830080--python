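{
  "comment": "Device unit prices (CNY) and mean per-episode utilization. Means are back-solved from the published base-case acquisition cells (stapler cost / unit price, cartridge cost / unit price) so that acquisition costs reproduce the published column to the yuan: powered 8327/6790=1.2263623, 17129/2441=7.0172061; manual 4790/3970=1.2065491, 18308/2441=7.5002048. Victor Medical utilization is assumed equal to the ECHELON manual arm.",
  "products": {
    "echelon_powered": {
      "name": "ECHELON powered (PSE45A / ECR45B)",
      "stapler_unit_price": 6790.0,
      "cartridge_unit_price": 2441.0,
      "mean_staplers": 1.2263623,
      "mean_cartridges": 7.0172061
    },
    "echelon_manual": {
      "name": "ECHELON manual (EC45A / ECR45B)",
      "stapler_unit_price": 3970.0,
      "cartridge_unit_price": 2441.0,
      "mean_staplers": 1.2065491,
      "mean_cartridges": 7.5002048
    },
    "victor_manual": {
      "name": "Victor Medical manual",
      "stapler_unit_price": 3800.0,
      "cartridge_unit_price": 2987.0,
      "mean_staplers": 1.2065491,
      "mean_cartridges": 7.5002048
    }
  }
}
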