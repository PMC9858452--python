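{
  "intercept": 1.834,
  "slope": 0.009,
  "aucr180": [
    1420.1730912309904,
    652.7962195690316,
    975.6712748508369,
    1004.6319485981974,
    1450.8609933267621,
    1563.6473650224789
  ],
  "sk_params": [
    {
      "c_inf": 10.380614233253002,
      "k": 0.02276926785496846
    },
    {
      "c_inf": 5.581105818889982,
      "k": 0.014748822259159008
    },
    {
      "c_inf": 6.565440552240904,
      "k": 0.03174935756880601
    },
    {
      "c_inf": 8.58445420926728,
      "k": 0.014767523952996322
    },
    {
      "c_inf": 11.174357746530296,
      "k": 0.019319930592336818
    },
    {
      "c_inf": 10.095771219933967,
      "k": 0.03978024319806241
    }
  ]
}
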