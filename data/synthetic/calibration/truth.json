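{
  "intercept": 1.834,
  "slope": 0.009,
  "aucr180": [
    2272.273409703772,
    795.3911260281111,
    1191.4282727146528,
    706.7117693870952,
    2123.569482026329,
    2179.0402952935465,
    1401.6248161434569,
    775.1714820765269
  ],
  "sk_params": [
    {
      "c_inf": 14.649238172897642,
      "k": 0.0401508981343247
    },
    {
      "c_inf": 11.162062547602417,
      "k": 0.00616399626792879
    },
    {
      "c_inf": 7.532487240591831,
      "k": 0.0458005945863858
    },
    {
      "c_inf": 4.753409852366162,
      "k": 0.031819153466662135
    },
    {
      "c_inf": 34.45361643051508,
      "k": 0.005035415106858417
    },
    {
      "c_inf": 14.180818358758087,
      "k": 0.03792549587238159
    },
    {
      "c_inf": 9.394550419351399,
      "k": 0.03236705467148748
    },
    {
      "c_inf": 7.566260053133787,
      "k": 0.01116757131879298
    }
  ]
}
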